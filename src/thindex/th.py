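"""The tumor-heterogeneity (TH) statistic: Shannon diversity on binned VAFs.

A tumor's somatic VAFs (percentages in [0, 100]) are assigned to ``N``
equal-width bins and the Shannon index

    H' = -sum_i p_i ln p_i

is computed over the bin probabilities ``p_i``.  The default bin width is
10 (so N = 10) and the index is reported in nats, unnormalized.  A cohort
is dichotomized at a cutoff (default 1.30, the colorectal study-cohort
average; ``cohort_cutoff`` recomputes a mean cutoff for any cohort), with
high TH defined as strictly exceeding the cutoff.

Bin-edge convention: bin ``i`` (1-based) covers ``[(i-1)*w, i*w)`` except
the last bin, which is closed at 100, so every VAF in [0, 100] maps to
exactly one bin.  Samples with zero mutations get an *undefined* TH
(NaN value, group ``"undefined"``) rather than 0, because H' = 0 has a
distinct meaning (a clonal VAF distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from thindex.variants import VafProfile

#: Default VAF bin width in percentage points.
DEFAULT_BIN_SIZE: float = 10.0
#: Default high/low TH cutoff (cohort-average TH of the reference cohort).
DEFAULT_CUTOFF: float = 1.30


@dataclass(frozen=True)
class BinnedVafDistribution:
    """Probability distribution of VAFs over equal-width bins."""

    bin_size: float
    probabilities: np.ndarray
    n_mutations: int

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


@dataclass(frozen=True)
class THIndex:
    """A TH index value with its binning metadata and classification.

    ``value`` is NaN and ``group`` is ``"undefined"`` iff the sample had no
    usable mutations.
    """

    value: float
    n_mutations: int
    bin_size: float
    group: str  # "high" | "low" | "undefined"

    @property
    def defined(self) -> bool:
        return self.group != "undefined"


def bin_vafs(vafs: Sequence[float], bin_size: float = DEFAULT_BIN_SIZE) -> BinnedVafDistribution:
    """Assign VAF percentages to equal-width bins and normalize to probabilities.

    ``bin_size`` must divide 100 evenly.  Empty input yields an all-zero
    probability vector with ``n_mutations == 0``, which ``shannon_index``
    rejects and ``compute_th_index`` maps to an undefined TH.
    """
    n_bins = 100.0 / bin_size
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_size {bin_size} does not divide 100")
    n_bins = int(round(n_bins))
    arr = np.asarray(list(vafs), dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 100.0):
        raise ValueError("VAF outside [0, 100]")
    counts = np.zeros(n_bins)
    if arr.size:
        idx = np.minimum((arr // bin_size).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
        probs = counts / arr.size
    else:
        probs = counts
    return BinnedVafDistribution(bin_size=bin_size, probabilities=probs, n_mutations=int(arr.size))


def shannon_index(dist: BinnedVafDistribution) -> float:
    """Shannon's H' = -sum p_i ln p_i in nats; 0*ln 0 contributes 0.

    Raises ``ValueError`` for an empty (all-zero) distribution — the TH
    index of a mutation-free sample is undefined, not 0.
    """
    p = np.asarray(dist.probabilities, dtype=float)
    if dist.n_mutations == 0 or p.sum() == 0.0:
        raise ValueError("TH index undefined: no mutations in distribution")
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("invalid probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum()) + 0.0  # + 0.0 normalizes -0.0


def classify_th(value: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Dichotomize a TH value: ``"high"`` iff value > cutoff, else ``"low"``.

    A value exactly at the cutoff is classified low, so "high TH" strictly
    exceeds the cohort reference.
    """
    if value < 0 or math.isnan(value):
        raise ValueError(f"invalid TH value {value}")
    return "high" if value > cutoff else "low"


def cohort_cutoff(values: Iterable[float]) -> float:
    """Cohort high/low cutoff: the arithmetic mean of defined TH values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot derive a cutoff from an empty cohort")
    if np.any(np.isnan(arr)):
        raise ValueError("undefined TH values in cutoff input")
    return float(arr.mean())


def compute_th_index(
    profile: VafProfile,
    bin_size: float = DEFAULT_BIN_SIZE,
    cutoff: float = DEFAULT_CUTOFF,
) -> THIndex:
    """Bin a sample's VAF profile, evaluate H' and classify it high/low."""
    dist = bin_vafs(profile.vafs, bin_size=bin_size)
    if dist.n_mutations == 0:
        return THIndex(value=float("nan"), n_mutations=0, bin_size=bin_size, group="undefined")
    value = shannon_index(dist)
    return THIndex(
        value=value,
        n_mutations=dist.n_mutations,
        bin_size=bin_size,
        group=classify_th(value, cutoff),
    )
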