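"""Tumor-purity estimation from panel germline SNPs.

A specimen with tumor purity ``P`` mixes tumor cells with diploid normal
cells.  At a germline-heterozygous SNP where the tumor carries ``X`` total
and ``Y`` alternative allele copies, the expected alternative allele
frequency is

    AAF = (P*Y + (1-P)) / (P*X + 2*(1-P)),

the normal contaminant contributing one alternative and two total copies.
Copy-neutral regions (X=2, Y=1) always give AAF = 1/2 and are therefore
uninformative; purity is recovered by inverting the model at SNP clusters
in copy-gain or copy-loss regions:

    P = (1 - 2*AAF) / (AAF*(X - 2) - Y + 1),

which is monotone (hence unique on [0, 1]) for every informative state.
Per sample, the maximum over per-cluster estimates is reported.

The pipeline is: (1) pre-screen heterozygous SNPs (BAF near 0.5), find the
most prominent peak of their read-coverage distribution — that modal
coverage marks copy-neutral regions; (2) classify each region's copy state
from its coverage ratio against the neutral level; (3) assign each
non-neutral region a tumor allele state (X, Y) from a small catalogue,
choosing the state whose implied purity best reproduces the region's
coverage ratio; (4) invert the AAF model per cluster and take the maximum.
Peak detection, the state catalogue and the coverage thresholds are this
package's reconstruction of the approach; they are deliberately simple and
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Candidate tumor allele states (X total copies, Y alternative copies)
#: considered for non-neutral SNP clusters.
STATE_CATALOGUE: tuple[tuple[int, int], ...] = (
    (1, 1),
    (1, 0),
    (3, 1),
    (3, 2),
    (4, 1),
    (4, 2),
    (4, 3),
)

DEFAULT_BAF_TOLERANCE = 0.15
DEFAULT_GAIN_RATIO = 1.25
DEFAULT_LOSS_RATIO = 0.75
#: Relative window around the modal coverage accepted as copy-neutral.
DEFAULT_PEAK_WINDOW = 0.10
#: How far outside [0, 1] an inverted purity may fall before the cluster is
#: flagged inconsistent instead of clamped.
DEFAULT_CLAMP_TOLERANCE = 0.10


@dataclass(frozen=True)
class SnpObservation:
    """One germline SNP with its read support in the tumor specimen."""

    chrom: str
    pos: int
    total_depth: int
    alt_depth: int
    region_id: str

    def __post_init__(self) -> None:
        if self.total_depth < 1:
            raise ValueError("total_depth must be >= 1")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError("alt_depth outside [0, total_depth]")

    @property
    def baf(self) -> float:
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class SnpCluster:
    """A group of SNPs in one region sharing a copy state and allele state."""

    region_id: str
    copy_state: str  # "neutral" | "gain" | "loss"
    X: int
    Y: int
    mean_aaf: float
    n_snps: int = 0
    coverage_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copy_state not in ("neutral", "gain", "loss"):
            raise ValueError(f"unknown copy_state {self.copy_state!r}")
        if self.copy_state == "neutral" and self.X != 2:
            raise ValueError("neutral cluster must have X == 2")
        if not 0 <= self.Y <= self.X:
            raise ValueError("require 0 <= Y <= X")
        if not 0.0 <= self.mean_aaf <= 1.0:
            raise ValueError("mean_aaf outside [0, 1]")


@dataclass
class PurityEstimate:
    """Sample-level purity with the per-cluster estimates behind it."""

    sample_id: str
    purity: float
    per_cluster_estimates: list[tuple[SnpCluster, float]] = field(default_factory=list)
    usable: bool = True


def predict_aaf(P: float, X: int, Y: int) -> float:
    """Expected alternative allele frequency at purity ``P`` and state (X, Y)."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if not 0 <= Y <= X:
        raise ValueError("require 0 <= Y <= X")
    denom = P * X + 2.0 * (1.0 - P)
    if denom <= 0.0:
        raise ValueError("degenerate state: no DNA at locus (P=1, X=0)")
    return (P * Y + (1.0 - P)) / denom


def invert_aaf(aaf: float, X: int, Y: int) -> Optional[float]:
    """Closed-form purity solving ``aaf == predict_aaf(P, X, Y)``.

    Returns ``None`` when the state is uninformative (the AAF does not
    depend on P, e.g. the copy-neutral state X=2, Y=1).  The returned value
    is *not* clamped; callers decide how to treat out-of-range solutions.
    """
    denom = aaf * (X - 2) - Y + 1
    if abs(denom) < 1e-12:
        return None
    return (1.0 - 2.0 * aaf) / denom


def find_copy_neutral_regions(
    snps: Sequence[SnpObservation],
    baf_tolerance: float = DEFAULT_BAF_TOLERANCE,
    peak_window: float = DEFAULT_PEAK_WINDOW,
    n_histogram_bins: int = 25,
) -> set[str]:
    """Identify copy-neutral regions from heterozygous-SNP coverage.

    SNPs whose BAF lies within ``baf_tolerance`` of 0.5 are pre-screened as
    heterozygous candidates; the most prominent peak of their read-coverage
    histogram gives the modal (copy-neutral) coverage.  Regions whose median
    screened-SNP coverage lies within ``peak_window`` (relative) of that
    peak are returned.  Returns an empty set when no SNP passes the screen —
    the sample is then unusable for purity estimation.
    """
    het = [s for s in snps if abs(s.baf - 0.5) <= baf_tolerance]
    if not het:
        return set()
    cov = np.array([s.total_depth for s in het], dtype=float)
    if cov.size == 1 or cov.min() == cov.max():
        peak = float(cov.mean())
    else:
        hist, edges = np.histogram(cov, bins=n_histogram_bins)
        i = int(hist.argmax())
        in_bin = cov[(cov >= edges[i]) & (cov <= edges[i + 1])]
        peak = float(in_bin.mean())
    neutral = set()
    regions: dict[str, list[float]] = {}
    for s in het:
        regions.setdefault(s.region_id, []).append(s.total_depth)
    for region_id, covs in regions.items():
        med = float(np.median(covs))
        if abs(med - peak) <= peak_window * peak:
            neutral.add(region_id)
    return neutral


def classify_copy_state(
    region_coverage: float,
    neutral_coverage: float,
    gain_ratio: float = DEFAULT_GAIN_RATIO,
    loss_ratio: float = DEFAULT_LOSS_RATIO,
) -> str:
    """Call gain/loss/neutral from the region's adjusted coverage ratio."""
    if region_coverage <= 0 or neutral_coverage <= 0:
        raise ValueError("coverage must be positive")
    ratio = region_coverage / neutral_coverage
    if ratio >= gain_ratio:
        return "gain"
    if ratio <= loss_ratio:
        return "loss"
    return "neutral"


def estimate_purity_at_cluster(
    cluster: SnpCluster,
    clamp_tolerance: float = DEFAULT_CLAMP_TOLERANCE,
) -> Optional[float]:
    """Invert the AAF model at one cluster; ``None`` if uninformative.

    Neutral clusters and states with AAF independent of purity return
    ``None``.  A solution outside [0, 1] by more than ``clamp_tolerance``
    marks the cluster inconsistent (``None``); smaller excursions (sampling
    noise) are clamped into [0, 1].
    """
    if cluster.copy_state == "neutral":
        return None
    p = invert_aaf(cluster.mean_aaf, cluster.X, cluster.Y)
    if p is None:
        return None
    if p < -clamp_tolerance or p > 1.0 + clamp_tolerance:
        logger.debug(
            "cluster %s state (%d,%d) inconsistent: P=%.3f",
            cluster.region_id,
            cluster.X,
            cluster.Y,
            p,
        )
        return None
    return float(min(max(p, 0.0), 1.0))


def assign_allele_state(
    copy_state: str,
    mean_aaf: float,
    coverage_ratio: float,
    clamp_tolerance: float = DEFAULT_CLAMP_TOLERANCE,
) -> Optional[tuple[int, int]]:
    """Pick the catalogue state (X, Y) best explaining a non-neutral cluster.

    Candidates are restricted to the copy-state direction (X < 2 for loss,
    X > 2 for gain).  Each candidate's purity is obtained by inverting the
    AAF model; candidates whose solution falls outside [0, 1] (beyond the
    clamp tolerance) are rejected, and among the survivors the state whose
    implied purity best reproduces the observed coverage ratio
    ``(P*X + 2*(1-P)) / 2`` wins.

    States with proportional excesses (X - 2, Y - 1) — e.g. (4, 3) at
    purity P and (3, 2) at purity 2P — predict identical AAF *and*
    coverage, so a single cluster cannot distinguish them.  Near-ties in
    the coverage fit are therefore resolved by parsimony: the state with
    the fewest copies wins.
    """
    if copy_state == "neutral":
        return (2, 1)
    candidates: list[tuple[float, int, int]] = []
    for X, Y in STATE_CATALOGUE:
        if copy_state == "gain" and X <= 2:
            continue
        if copy_state == "loss" and X >= 2:
            continue
        p = invert_aaf(mean_aaf, X, Y)
        if p is None or p < -clamp_tolerance or p > 1.0 + clamp_tolerance:
            continue
        p = min(max(p, 0.0), 1.0)
        predicted_ratio = (p * X + 2.0 * (1.0 - p)) / 2.0
        candidates.append((abs(predicted_ratio - coverage_ratio), X, Y))
    if not candidates:
        return None
    best_err = min(err for err, _, _ in candidates)
    tied = [(X, Y) for err, X, Y in candidates if err <= best_err + 0.1]
    return min(tied)


def estimate_sample_purity(
    clusters: Sequence[SnpCluster],
    sample_id: str = "",
    aggregate: str = "max",
    clamp_tolerance: float = DEFAULT_CLAMP_TOLERANCE,
) -> PurityEstimate:
    """Combine per-cluster purity estimates into one sample-level value.

    ``aggregate="max"`` (default) takes the maximum over informative
    clusters; ``"mean"`` averages them instead (less biased under noise but
    not the default behavior).  With no informative cluster the estimate is
    marked unusable (purity NaN).
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    per_cluster: list[tuple[SnpCluster, float]] = []
    for cluster in clusters:
        p = estimate_purity_at_cluster(cluster, clamp_tolerance=clamp_tolerance)
        if p is not None:
            per_cluster.append((cluster, p))
    if not per_cluster:
        return PurityEstimate(sample_id=sample_id, purity=float("nan"), usable=False)
    values = [p for _, p in per_cluster]
    purity = max(values) if aggregate == "max" else float(np.mean(values))
    return PurityEstimate(
        sample_id=sample_id,
        purity=purity,
        per_cluster_estimates=per_cluster,
        usable=True,
    )


def build_snp_clusters(
    snps: Sequence[SnpObservation],
    baf_tolerance: float = DEFAULT_BAF_TOLERANCE,
    gain_ratio: float = DEFAULT_GAIN_RATIO,
    loss_ratio: float = DEFAULT_LOSS_RATIO,
    peak_window: float = DEFAULT_PEAK_WINDOW,
    clamp_tolerance: float = DEFAULT_CLAMP_TOLERANCE,
) -> list[SnpCluster]:
    """Group SNPs by region, call copy states and assign allele states.

    Returns one cluster per region with a resolvable state; regions whose
    AAF is inconsistent with every catalogue state are dropped with a debug
    log.  An empty list signals an unusable sample.
    """
    if not snps:
        return []
    neutral_ids = find_copy_neutral_regions(
        snps, baf_tolerance=baf_tolerance, peak_window=peak_window
    )
    if not neutral_ids:
        return []
    regions: dict[str, list[SnpObservation]] = {}
    for s in snps:
        regions.setdefault(s.region_id, []).append(s)
    neutral_cov = float(
        np.median([np.median([s.total_depth for s in regions[r]]) for r in neutral_ids])
    )
    clusters: list[SnpCluster] = []
    for region_id in sorted(regions):
        obs = regions[region_id]
        med_cov = float(np.median([s.total_depth for s in obs]))
        if region_id in neutral_ids:
            state = "neutral"
        else:
            state = classify_copy_state(
                med_cov, neutral_cov, gain_ratio=gain_ratio, loss_ratio=loss_ratio
            )
        ratio = med_cov / neutral_cov
        mean_aaf = float(np.mean([s.baf for s in obs]))
        xy = assign_allele_state(state, mean_aaf, ratio, clamp_tolerance=clamp_tolerance)
        if xy is None:
            logger.debug("region %s: no catalogue state fits AAF %.3f", region_id, mean_aaf)
            continue
        clusters.append(
            SnpCluster(
                region_id=region_id,
                copy_state=state,
                X=xy[0],
                Y=xy[1],
                mean_aaf=mean_aaf,
                n_snps=len(obs),
                coverage_ratio=ratio,
            )
        )
    return clusters


def estimate_purity_from_snps(
    snps: Sequence[SnpObservation],
    sample_id: str = "",
    aggregate: str = "max",
    **cluster_kwargs,
) -> PurityEstimate:
    """Full per-sample pipeline: SNP observations -> PurityEstimate."""
    clusters = build_snp_clusters(snps, **cluster_kwargs)
    return estimate_sample_purity(clusters, sample_id=sample_id, aggregate=aggregate)
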