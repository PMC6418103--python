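"""Methodological evaluations of the TH index.

Covers the robustness and validity checks a panel-based heterogeneity
statistic needs before clinical use: how the index degrades as the gene
panel shrinks (down-sampling curve), whether it tracks the number of
subclones (rank-sum comparison of lower- vs higher-clonality tumors), and
whether it is confounded by tumor purity or raw mutation count (Spearman
correlations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from thindex.th import DEFAULT_BIN_SIZE, compute_th_index
from thindex.variants import PanelDefinition, VariantRecord, extract_vaf_profile


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class DownsampleResult:
    """Spearman correlation of down-sampled vs reference TH for one draw."""

    k: int
    replicate: int
    spearman_r: float  # NaN when the cell was not evaluable
    n_samples: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    median_lower: float
    median_higher: float
    n_lower: int
    n_higher: int


def downsample_panel(panel: PanelDefinition, k: int, seed) -> PanelDefinition:
    """Uniform random subset of ``k`` panel genes, deterministic per seed."""
    if not 1 <= k <= len(panel):
        raise ValueError(f"k={k} outside [1, {len(panel)}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = rng.choice(sorted(panel.genes), size=k, replace=False)
    return PanelDefinition(name=f"{panel.name}_k{k}", genes=frozenset(genes.tolist()))


def spearman_correlation(a: Sequence[float], b: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(a, b)
    return SpearmanResult(r=float(res.statistic), pvalue=float(res.pvalue), n=int(a.size))


def downsampling_curve(
    variant_sets: Sequence[Sequence[VariantRecord]],
    panel: PanelDefinition,
    reference_th: Sequence[float],
    ks: Sequence[int],
    replicates: int = 20,
    seed=None,
    bin_size: float = DEFAULT_BIN_SIZE,
) -> list[DownsampleResult]:
    """Recompute TH on random gene subsets and correlate with the reference.

    For each panel size ``k`` and replicate, a uniform gene subset is drawn,
    every sample's TH is recomputed on the reduced panel, and the Spearman
    correlation against ``reference_th`` is recorded.  Samples whose reduced
    profile is empty are dropped pairwise for that draw (never assigned TH
    0); a draw with fewer than 3 evaluable samples, or a constant TH vector,
    is reported with ``spearman_r`` NaN rather than fabricated.
    """
    if len(variant_sets) != len(reference_th):
        raise ValueError("one reference TH per variant set required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reference = np.asarray(reference_th, dtype=float)
    results: list[DownsampleResult] = []
    for k in ks:
        for rep in range(replicates):
            sub = downsample_panel(panel, k, rng)
            th_vals, ref_vals = [], []
            for records, ref in zip(variant_sets, reference):
                profile = extract_vaf_profile(records, sub, sample_id="")
                if profile.n_mutations == 0 or np.isnan(ref):
                    continue
                th_vals.append(compute_th_index(profile, bin_size=bin_size).value)
                ref_vals.append(ref)
            if len(th_vals) < 3 or np.ptp(th_vals) == 0 or np.ptp(ref_vals) == 0:
                r = float("nan")
            else:
                r = spearman_correlation(th_vals, ref_vals).r
            results.append(
                DownsampleResult(k=int(k), replicate=rep, spearman_r=r, n_samples=len(th_vals))
            )
    return results


def median_curve(results: Sequence[DownsampleResult]) -> dict[int, float]:
    """Median Spearman r per panel size, ignoring non-evaluable draws."""
    by_k: dict[int, list[float]] = {}
    for res in results:
        if not np.isnan(res.spearman_r):
            by_k.setdefault(res.k, []).append(res.spearman_r)
    return {k: float(np.median(v)) for k, v in sorted(by_k.items())}


def compare_by_clonality(
    th: Sequence[float],
    n_subclones: Sequence[int],
    split: Optional[int] = None,
) -> RankSumResult:
    """One-sided rank-sum test: do higher-clonality tumors have higher TH?

    Tumors with ``n_subclones <= split`` form the lower-clonality group and
    the rest the higher-clonality group (default split: cohort median
    subclone count).  Wilcoxon rank-sum with alternative
    higher-clonal > lower-clonal.  With every TH value identical the test
    carries no evidence and p = 1 by convention.
    """
    th = np.asarray(th, dtype=float)
    clones = np.asarray(n_subclones, dtype=int)
    if th.shape != clones.shape:
        raise ValueError("paired vectors must have equal length")
    if split is None:
        split = int(np.median(clones))
    lower = th[clones <= split]
    higher = th[clones > split]
    if lower.size == 0 or higher.size == 0:
        raise ValueError(f"split {split} leaves an empty group")
    if np.ptp(th) == 0:
        return RankSumResult(
            statistic=float(lower.size * higher.size / 2.0),
            pvalue=1.0,
            median_lower=float(np.median(lower)),
            median_higher=float(np.median(higher)),
            n_lower=int(lower.size),
            n_higher=int(higher.size),
        )
    res = stats.mannwhitneyu(higher, lower, alternative="greater", use_continuity=False)
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_lower=float(np.median(lower)),
        median_higher=float(np.median(higher)),
        n_lower=int(lower.size),
        n_higher=int(higher.size),
    )


def th_confounder_check(
    th: Sequence[float],
    purity: Sequence[float],
    n_mutations: Sequence[int],
) -> tuple[SpearmanResult, SpearmanResult]:
    """Spearman correlations of TH against purity and against mutation count."""
    th = np.asarray(th, dtype=float)
    if len(th) != len(purity) or len(th) != len(n_mutations):
        raise ValueError("paired vectors must have equal length")
    if len(th) < 3:
        raise ValueError("need at least 3 samples")
    return (
        spearman_correlation(th, purity),
        spearman_correlation(th, np.asarray(n_mutations, dtype=float)),
    )
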