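"""Synthetic subclonal tumors and cohorts for validating the TH pipeline.

The generative model is deliberately the simplest one under which the TH
index is meaningful:

- A tumor is a nested set of clones.  The founding clone has cancer-cell
  fraction f = 1; each subclone's fraction is strictly below its parent's.
- Mutations are diploid and heterozygous, so a mutation private to clone c
  in a specimen of purity P has expected VAF ``100 * P * f_c / 2``.
- Per-site sequencing depth is Poisson around the sample's mean depth with
  a floor of 30 reads; the alternative read count is Binomial(depth,
  expected VAF / 100).
- Copy number does not interact with somatic VAFs; germline SNPs for the
  purity module are generated separately (``simulate_germline_snps``) with
  explicit tumor allele states (X, Y).

Cohorts add clinical structure: pathological stage drawn from the
reference case mix (3.3 / 9.9 / 41.1 / 45.7 % for stages I-IV), a
stage-increasing subclone count in 1-6, purity uniform in [0.2, 1.0], mean
depth uniform in [100, 1000], and exponential survival with proportional
hazards on the high-TH indicator and the clinical/genomic flags.  The TH
group entering the hazard is the one the pipeline itself computes
(cohort-mean cutoff), so the simulated prognostic signal is attached to
the measured statistic, exactly as downstream analyses assume.

All randomness flows from one ``numpy`` Generator; the same seed and
configuration reproduce the cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from thindex.purity import SnpObservation, predict_aaf
from thindex.th import DEFAULT_BIN_SIZE, classify_th, cohort_cutoff, compute_th_index
from thindex.variants import PanelDefinition, VafProfile, VariantRecord, variants_to_frame

STAGES = ("I", "II", "III", "IV")

_DEPTH_FLOOR = 30


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ClonalArchitecture:
    """Clone fractions of a tumor, founding clone first at f = 1.

    ``mutation_weights`` are per-clone relative mutation burdens used when a
    target mutation count is distributed over clones.
    """

    clone_fractions: tuple[float, ...]
    mutation_weights: tuple[int, ...]

    def __post_init__(self) -> None:
        f = self.clone_fractions
        if not f or not math.isclose(f[0], 1.0):
            raise ValueError("founding clone fraction must be 1")
        for parent, child in zip(f, f[1:]):
            if not 0.0 < child < parent:
                raise ValueError("subclone fractions must be nested (strictly decreasing)")
        if len(self.mutation_weights) != len(f):
            raise ValueError("one mutation weight per clone required")

    @property
    def n_subclones(self) -> int:
        return len(self.clone_fractions)


@dataclass
class SimulatedTumor:
    """A simulated tumor: truth (architecture, purity) plus generated variants."""

    sample_id: str
    architecture: ClonalArchitecture
    purity: float
    depth: float
    variants: list[VariantRecord]
    true_th_inputs: list[float]  # expected (noise-free) VAFs per mutation

    def vaf_profile(self, panel: PanelDefinition) -> VafProfile:
        from thindex.variants import extract_vaf_profile

        return extract_vaf_profile(self.variants, panel, self.sample_id)


@dataclass
class CohortRecord:
    """Clinical covariates and outcome for one simulated patient."""

    sample_id: str
    stage: str
    survival_time: float
    event: bool
    li: bool
    vi: bool
    pni: bool
    tb: bool
    apc: bool
    kras: bool
    tp53: bool
    th_value: float
    th_group: str
    n_subclones: int
    purity: float


def simulate_architecture(n_subclones: int, seed) -> ClonalArchitecture:
    """Draw a nested clonal architecture with ``n_subclones`` clones total.

    The founding clone sits at fraction 1; the remaining fractions are
    uniform draws on (0, 1), sorted in decreasing order so each subclone
    nests inside the previous one.  Per-clone mutation weights are small
    uniform integers.  Deterministic for a given seed.
    """
    if n_subclones < 1:
        raise ValueError("n_subclones must be >= 1")
    rng = _as_rng(seed)
    children = np.sort(rng.uniform(0.05, 0.95, size=n_subclones - 1))[::-1]
    fractions = (1.0, *children.tolist())
    weights = tuple(int(w) for w in rng.integers(1, 4, size=n_subclones))
    return ClonalArchitecture(clone_fractions=fractions, mutation_weights=weights)


def _distribute(n: int, weights: Sequence[int]) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` mutations over clones."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    rest = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rest]] += 1
    return counts


def simulate_tumor(
    arch: ClonalArchitecture,
    purity: float,
    depth: float,
    n_mutations: int,
    panel: PanelDefinition,
    seed,
    sample_id: str = "S0",
) -> SimulatedTumor:
    """Generate read-count data for one tumor.

    Mutations are apportioned to clones by the architecture's weights; each
    mutation gets a random panel gene, expected VAF ``100 * purity * f / 2``
    and a Binomial alternative-read draw at Poisson per-site depth
    (floored at 30 reads).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if depth <= 0 or n_mutations < 0:
        raise ValueError("depth must be positive and n_mutations non-negative")
    rng = _as_rng(seed)
    genes = sorted(panel.genes)
    counts = _distribute(n_mutations, arch.mutation_weights)
    clone_of = np.repeat(np.arange(arch.n_subclones), counts)
    fractions = np.asarray(arch.clone_fractions)[clone_of]
    expected_vaf = 100.0 * purity * fractions / 2.0
    site_depth = np.maximum(rng.poisson(depth, size=n_mutations), _DEPTH_FLOOR)
    alt = rng.binomial(site_depth, expected_vaf / 100.0)
    gene_idx = rng.integers(0, len(genes), size=n_mutations)
    variants = []
    for i in range(n_mutations):
        d, a = int(site_depth[i]), int(alt[i])
        variants.append(
            VariantRecord(
                chrom="chr1",
                pos=1000 * (i + 1),
                ref_allele="A",
                alt_allele="T",
                gene=genes[int(gene_idx[i])],
                ref_count=d - a,
                alt_count=a,
                vaf=100.0 * a / d,
                sample_id=sample_id,
            )
        )
    return SimulatedTumor(
        sample_id=sample_id,
        architecture=arch,
        purity=purity,
        depth=depth,
        variants=variants,
        true_th_inputs=expected_vaf.tolist(),
    )


def simulate_germline_snps(
    purity: float,
    states: Sequence[tuple[int, int]],
    snps_per_region: int = 20,
    depth: float = 500.0,
    seed=None,
    n_neutral_regions: int = 6,
) -> list[SnpObservation]:
    """Germline heterozygous SNPs for the purity module.

    ``states`` lists the (X, Y) tumor allele states of the non-neutral
    regions; ``n_neutral_regions`` copy-neutral regions (X=2, Y=1) are
    added so the modal-coverage peak is well defined.  Per-SNP depth is
    Poisson around ``depth`` scaled by the region's relative DNA content
    ``(P*X + 2*(1-P)) / 2``; alternative reads are Binomial at the model
    AAF.
    """
    rng = _as_rng(seed)
    snps: list[SnpObservation] = []
    regions = [("neutral%d" % i, 2, 1) for i in range(n_neutral_regions)]
    regions += [("altered%d" % i, X, Y) for i, (X, Y) in enumerate(states)]
    pos = 0
    for region_id, X, Y in regions:
        aaf = predict_aaf(purity, X, Y)
        scale = (purity * X + 2.0 * (1.0 - purity)) / 2.0
        depths = np.maximum(rng.poisson(depth * scale, size=snps_per_region), 1)
        alts = rng.binomial(depths, aaf)
        for d, a in zip(depths, alts):
            pos += 10_000
            snps.append(
                SnpObservation(
                    chrom="chr1",
                    pos=pos,
                    total_depth=int(d),
                    alt_depth=int(a),
                    region_id=region_id,
                )
            )
    return snps


def default_panel(n_genes: int = 381, name: str = "panel381") -> PanelDefinition:
    """A synthetic panel of ``n_genes`` gene symbols (G0001, G0002, ...)."""
    return PanelDefinition(name=name, genes=frozenset(f"G{i:04d}" for i in range(1, n_genes + 1)))


@dataclass
class CohortConfig:
    """Study conditions for cohort simulation.

    Defaults mirror the reference colorectal cohort: 304 patients, stage
    mix 3.3 / 9.9 / 41.1 / 45.7 %, tumor purity in [0.2, 1.0], mean
    per-mutation depth in [100, 1000] reads, 1-6 clones per tumor with a
    stage-increasing mean, and proportional-hazards survival in months with
    hazard ratio 2 for high TH and 1.5 per adverse clinical flag.
    """

    n_samples: int = 304
    stage_probs: tuple[float, ...] = (0.033, 0.099, 0.411, 0.457)
    purity_range: tuple[float, float] = (0.2, 1.0)
    depth_range: tuple[float, float] = (100.0, 1000.0)
    mean_mutations: float = 25.0
    min_mutations: int = 3
    max_subclones: int = 6
    # P(extra clone) per stage; subclones = 1 + Binomial(max-1, p_stage)
    stage_subclone_p: tuple[float, ...] = (0.15, 0.30, 0.45, 0.60)
    panel_size: int = 381
    bin_size: float = DEFAULT_BIN_SIZE
    # survival model
    beta_th: float = math.log(2.0)
    beta_features: dict = field(
        default_factory=lambda: {
            "li": math.log(1.5),
            "vi": math.log(1.5),
            "pni": math.log(1.5),
            "tb": math.log(1.5),
            "apc": math.log(1.2),
            "kras": math.log(1.2),
            "tp53": math.log(1.2),
        }
    )
    feature_prevalence: dict = field(
        default_factory=lambda: {
            "li": 0.578,
            "vi": 0.461,
            "pni": 0.406,
            "tb": 0.721,
            "apc": 0.70,
            "kras": 0.45,
            "tp53": 0.60,
        }
    )
    baseline_hazard: float = math.log(2.0) / 24.0  # median 24 months at lp = 0
    censoring_rate: float = 0.30

    def __post_init__(self) -> None:
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        if len(self.stage_probs) != len(STAGES):
            raise ValueError("one stage probability per stage required")
        if len(self.stage_subclone_p) != len(STAGES):
            raise ValueError("one subclone propensity per stage required")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stage_probs", "depth_range", "purity_range", "stage_subclone_p"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    seed=None,
    panel: Optional[PanelDefinition] = None,
) -> tuple[list[SimulatedTumor], list[CohortRecord]]:
    """Simulate a full cohort: tumors, TH classification and outcomes.

    TH indices are computed from the generated read counts with the
    package's own pipeline and dichotomized at the cohort mean; survival
    times are exponential with log-hazard
    ``beta_th * 1[high TH] + sum_k beta_k * flag_k`` and independent
    exponential censoring tuned to the configured censoring fraction.
    Samples whose TH is undefined (no mutations) are classified low for the
    hazard model and flagged in the record.
    """
    config = config or CohortConfig()
    rng = _as_rng(seed)
    if panel is None:
        panel = default_panel(config.panel_size)

    n = config.n_samples
    stage_idx = rng.choice(len(STAGES), size=n, p=np.asarray(config.stage_probs))
    purities = rng.uniform(*config.purity_range, size=n)
    depths = rng.uniform(*config.depth_range, size=n)
    n_mut = np.maximum(rng.poisson(config.mean_mutations, size=n), config.min_mutations)
    flags = {
        name: rng.random(n) < p for name, p in config.feature_prevalence.items()
    }

    tumors: list[SimulatedTumor] = []
    for i in range(n):
        p_extra = config.stage_subclone_p[stage_idx[i]]
        k = 1 + int(rng.binomial(config.max_subclones - 1, p_extra))
        arch = simulate_architecture(k, rng)
        tumors.append(
            simulate_tumor(
                arch,
                purity=float(purities[i]),
                depth=float(depths[i]),
                n_mutations=int(n_mut[i]),
                panel=panel,
                seed=rng,
                sample_id=f"S{i:04d}",
            )
        )

    th_values = np.array(
        [
            compute_th_index(t.vaf_profile(panel), bin_size=config.bin_size).value
            for t in tumors
        ]
    )
    defined = ~np.isnan(th_values)
    cutoff = cohort_cutoff(th_values[defined]) if defined.any() else 0.0
    groups = [
        classify_th(v, cutoff) if ok else "undefined"
        for v, ok in zip(th_values, defined)
    ]

    records: list[CohortRecord] = []
    for i, tumor in enumerate(tumors):
        lp = config.beta_th * (groups[i] == "high")
        for name, beta in config.beta_features.items():
            lp += beta * bool(flags[name][i])
        rate = config.baseline_hazard * math.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        if config.censoring_rate > 0:
            c_rate = rate * config.censoring_rate / (1.0 - config.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = math.inf
        time = min(t_event, t_cens)
        records.append(
            CohortRecord(
                sample_id=tumor.sample_id,
                stage=STAGES[stage_idx[i]],
                survival_time=float(time),
                event=bool(t_event <= t_cens),
                li=bool(flags["li"][i]),
                vi=bool(flags["vi"][i]),
                pni=bool(flags["pni"][i]),
                tb=bool(flags["tb"][i]),
                apc=bool(flags["apc"][i]),
                kras=bool(flags["kras"][i]),
                tp53=bool(flags["tp53"][i]),
                th_value=float(th_values[i]),
                th_group=groups[i],
                n_subclones=tumor.architecture.n_subclones,
                purity=tumor.purity,
            )
        )
    return tumors, records


def cohort_clinical_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Clinical table (one row per patient) for the prognosis module."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "stage": [r.stage for r in records],
            "time": [r.survival_time for r in records],
            "event": [r.event for r in records],
            "LI": [r.li for r in records],
            "VI": [r.vi for r in records],
            "PNI": [r.pni for r in records],
            "TB": [r.tb for r in records],
            "APC": [r.apc for r in records],
            "KRAS": [r.kras for r in records],
            "TP53": [r.tp53 for r in records],
            "th_value": [r.th_value for r in records],
            "th_group": [r.th_group for r in records],
            "n_subclones": [r.n_subclones for r in records],
            "purity": [r.purity for r in records],
        }
    )


def write_cohort(
    tumors: Sequence[SimulatedTumor],
    records: Sequence[CohortRecord],
    out_dir: str | Path,
) -> None:
    """Write the cohort as a variant TSV and a clinical CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_variants = [v for t in tumors for v in t.variants]
    variants_to_frame(all_variants).to_csv(out / "variants.tsv", sep="\t", index=False)
    cohort_clinical_frame(records).to_csv(out / "clinical.csv", index=False)
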