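"""Clinical-outcome analyses for the TH index.

- ``linear_by_linear_trend``: the Mantel-Haenszel one-degree-of-freedom
  trend test M^2 = (n - 1) r^2 for an ordered stage x binary high-TH table
  (stage scores 1..K, equally spaced).
- ``km_logrank``: Kaplan-Meier curves and the log-rank test between TH (or
  arbitrary) groups.
- ``stratified_feature_analysis``: four-way stratification by a clinical
  feature and the TH group, testing the two extreme strata
  (feature-negative & low TH vs feature-positive & high TH) against each
  other.
- ``c_index_evaluation``: Harrell's C for named covariate sets over
  repeated random subsamples (Cox proportional hazards, Efron ties), the
  resampling distribution used to ask whether adding the TH group improves
  risk prediction; ``compare_with_without_th`` runs the Welch t-test
  between two such distributions.

Kaplan-Meier / log-rank / Cox machinery comes from ``lifelines``; the
trend statistic is computed directly from the contingency table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageThTable:
    """Counts of patients and of high-TH patients per ordered stage."""

    stages: tuple[str, ...]
    n_per_stage: tuple[int, ...]
    n_high_th: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        if not len(self.stages) == len(self.n_per_stage) == len(self.n_high_th):
            raise ValueError("ragged stage table")
        for n, h in zip(self.n_per_stage, self.n_high_th):
            if n <= 0:
                raise ValueError("every stage must contain at least one patient")
            if not 0 <= h <= n:
                raise ValueError("high-TH count outside [0, n]")

    @property
    def n(self) -> int:
        return sum(self.n_per_stage)


@dataclass(frozen=True)
class TrendResult:
    statistic: float  # M^2
    pvalue: float
    r: float  # Pearson correlation between stage score and high-TH indicator


@dataclass
class KMResult:
    """Survival curves per group plus a log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    statistic: float
    pvalue: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class StratifiedResult:
    """Four-group feature x TH stratification with the extreme-group test."""

    curves: dict[str, pd.DataFrame]
    statistic: float
    pvalue: float
    evaluable: bool
    n_excluded_missing: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class RiskModelSpec:
    """Covariate sets and resampling settings for C-index evaluation."""

    feature_sets: dict[str, list[str]]
    iterations: int = 500
    subsample_fraction: float = 0.8
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    pvalue: float
    mean_difference: float
    flagged: bool = False


def linear_by_linear_trend(table: StageThTable) -> TrendResult:
    """Mantel-Haenszel linear-by-linear association test.

    With integer stage scores 1..K and the binary high-TH indicator, the
    statistic is M^2 = (n - 1) r^2 where r is the Pearson correlation over
    all n patients; p comes from the chi-square distribution with 1 df.
    A table with no variation in either margin has no trend (statistic 0,
    p = 1).
    """
    scores = np.arange(1, len(table.stages) + 1, dtype=float)
    n = table.n
    n_i = np.asarray(table.n_per_stage, dtype=float)
    h_i = np.asarray(table.n_high_th, dtype=float)
    sum_x = float(scores @ n_i)
    sum_x2 = float((scores**2) @ n_i)
    sum_y = float(h_i.sum())
    sum_xy = float(scores @ h_i)
    var_x = n * sum_x2 - sum_x**2
    var_y = n * sum_y - sum_y**2  # y is 0/1 so sum y^2 == sum y
    if var_x <= 0 or var_y <= 0:
        return TrendResult(statistic=0.0, pvalue=1.0, r=0.0)
    r = (n * sum_xy - sum_x * sum_y) / math.sqrt(var_x * var_y)
    m2 = (n - 1) * r**2
    return TrendResult(statistic=m2, pvalue=float(stats.chi2.sf(m2, df=1)), r=r)


def _km_curve(time: np.ndarray, event: np.ndarray, label: str) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=label)
    table = kmf.event_table
    return pd.DataFrame(
        {
            "time": kmf.survival_function_.index.values,
            "survival": kmf.survival_function_[label].values,
            "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).values,
        }
    )


def km_logrank(
    time: Sequence[float],
    event: Sequence[bool],
    group: Sequence[str],
) -> KMResult:
    """Kaplan-Meier curves per group and the log-rank test between groups.

    Two groups use the standard two-sample log-rank statistic; more use its
    multivariate generalization.  A comparison with no observed events is
    degenerate: the curves are still returned, p is NaN and a warning is
    recorded.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    labels = sorted(pd.unique(group).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    curves = {
        lab: _km_curve(time[group == lab], event[group == lab], lab) for lab in labels
    }
    warnings: list[str] = []
    if event.sum() == 0:
        warnings.append("no events observed; log-rank test degenerate")
        return KMResult(curves=curves, statistic=float("nan"), pvalue=float("nan"), warnings=warnings)
    for lab in labels:
        if event[group == lab].sum() == 0:
            warnings.append(f"group {lab!r} is fully censored")
    if len(labels) == 2:
        res = logrank_test(
            time[group == labels[0]],
            time[group == labels[1]],
            event_observed_A=event[group == labels[0]],
            event_observed_B=event[group == labels[1]],
        )
    else:
        res = multivariate_logrank_test(time, group, event)
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        warnings=warnings,
    )


def stratified_feature_analysis(
    cohort: pd.DataFrame,
    feature: str,
    th_group_col: str = "th_group",
    time_col: str = "time",
    event_col: str = "event",
    min_group_size: int = 5,
) -> StratifiedResult:
    """Stratify survival by a clinical feature and the TH group.

    Patients missing the feature or the TH group are excluded listwise
    (count reported).  Four Kaplan-Meier curves are produced, labelled
    ``"<feature>-/low"`` .. ``"<feature>+/high"``; the log-rank test
    compares only the two extreme strata, feature-negative & low TH vs
    feature-positive & high TH.  If either extreme stratum is empty the
    analysis is reported as not evaluable; small strata raise a low-power
    warning.
    """
    df = cohort.copy()
    mask = df[feature].notna() & df[th_group_col].isin(["high", "low"])
    n_excluded = int((~mask).sum())
    df = df[mask]
    warnings: list[str] = []

    def label(feat_pos: bool, th: str) -> str:
        return f"{feature}{'+' if feat_pos else '-'}/{th}"

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for feat_pos in (False, True):
        for th in ("low", "high"):
            sel = (df[feature].astype(bool) == feat_pos) & (df[th_group_col] == th)
            sizes[label(feat_pos, th)] = int(sel.sum())
            if sel.sum() > 0:
                curves[label(feat_pos, th)] = _km_curve(
                    df.loc[sel, time_col].to_numpy(float),
                    df.loc[sel, event_col].to_numpy(bool),
                    label(feat_pos, th),
                )
    feat_levels = set(df[feature].astype(bool))
    if len(feat_levels) == 1:
        # constant feature: the four strata collapse to two and the extreme
        # comparison reduces to the plain TH-group comparison
        level = feat_levels.pop()
        warnings.append(f"feature {feature!r} is constant; comparison reduces to TH groups")
        neg_level, pos_level = level, level
    else:
        neg_level, pos_level = False, True
    lo_key, hi_key = label(neg_level, "low"), label(pos_level, "high")
    if sizes[lo_key] == 0 or sizes[hi_key] == 0:
        return StratifiedResult(
            curves=curves,
            statistic=float("nan"),
            pvalue=float("nan"),
            evaluable=False,
            n_excluded_missing=n_excluded,
            warnings=["an extreme stratum is empty; comparison not evaluable"],
        )
    for key, size in sizes.items():
        if 0 < size < min_group_size:
            warnings.append(f"stratum {key} has only {size} patients (low power)")
    lo = (df[feature].astype(bool) == neg_level) & (df[th_group_col] == "low")
    hi = (df[feature].astype(bool) == pos_level) & (df[th_group_col] == "high")
    res = logrank_test(
        df.loc[lo, time_col].to_numpy(float),
        df.loc[hi, time_col].to_numpy(float),
        event_observed_A=df.loc[lo, event_col].to_numpy(bool),
        event_observed_B=df.loc[hi, event_col].to_numpy(bool),
    )
    return StratifiedResult(
        curves=curves,
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        evaluable=True,
        n_excluded_missing=n_excluded,
        warnings=warnings,
    )


def harrell_c_index(
    time: Sequence[float],
    event: Sequence[bool],
    risk_score: Sequence[float],
) -> float:
    """Harrell's concordance index of a risk score (higher score = higher risk)."""
    from lifelines.utils import concordance_index

    # concordance_index expects higher predicted value = longer survival
    return float(concordance_index(time, -np.asarray(risk_score, float), event))


def c_index_evaluation(
    cohort: pd.DataFrame,
    spec: RiskModelSpec,
    time_col: str = "time",
    event_col: str = "event",
    max_skip_fraction: float = 0.10,
) -> dict[str, np.ndarray]:
    """Resampling distribution of Harrell's C per covariate set.

    Each iteration draws a random subsample (``subsample_fraction``,
    without replacement; redrawn, with a log, if it contains no event),
    fits a Cox proportional-hazards model (Efron tie handling) on the named
    covariates and records the model's concordance index on that
    subsample.  Iterations with a non-convergent fit are skipped and
    logged; more than ``max_skip_fraction`` skips for a covariate set is a
    hard failure.
    """
    for name, cols in spec.feature_sets.items():
        missing = [c for c in cols if c not in cohort.columns]
        if missing:
            raise ValueError(f"feature set {name!r}: missing covariates {missing}")
    rng = np.random.default_rng(spec.seed)
    n = len(cohort)
    m = max(2, int(round(spec.subsample_fraction * n)))
    subsamples = []
    for _ in range(spec.iterations):
        for _attempt in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if cohort.iloc[idx][event_col].sum() >= 1:
                break
            logger.info("redrew an event-free subsample")
        subsamples.append(idx)

    out: dict[str, np.ndarray] = {}
    for name, cols in spec.feature_sets.items():
        values: list[float] = []
        skipped = 0
        for idx in subsamples:
            sub = cohort.iloc[idx][[time_col, event_col] + list(cols)].astype(float)
            try:
                fitter = CoxPHFitter()
                fitter.fit(sub, duration_col=time_col, event_col=event_col)
                values.append(float(fitter.concordance_index_))
            except Exception as exc:  # convergence / singularity
                skipped += 1
                logger.warning("feature set %r: skipped iteration (%s)", name, exc)
        if skipped > max_skip_fraction * spec.iterations:
            raise RuntimeError(
                f"feature set {name!r}: {skipped}/{spec.iterations} fits failed"
            )
        out[name] = np.asarray(values)
    return out


def compare_with_without_th(
    c_with: Sequence[float],
    c_without: Sequence[float],
) -> TTestResult:
    """Welch two-sample t-test between C-index distributions.

    Degenerate case: both vectors constant and equal — no evidence either
    way, returned as p = 1 with a flag.
    """
    a = np.asarray(c_with, dtype=float)
    b = np.asarray(c_without, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    mean_diff = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        if mean_diff == 0:
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), pvalue=1.0,
                               mean_difference=0.0, flagged=True)
        return TTestResult(t=math.inf if mean_diff > 0 else -math.inf,
                           df=float(a.size + b.size - 2), pvalue=0.0,
                           mean_difference=mean_diff, flagged=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(getattr(res, "df", float("nan")))
    return TTestResult(
        t=float(res.statistic),
        df=df,
        pvalue=float(res.pvalue),
        mean_difference=mean_diff,
    )
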