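"""Stage trend test, Kaplan-Meier / log-rank, stratification and C-index."""

import math

import numpy as np
import pandas as pd
import pytest

from thindex.prognosis import (
    RiskModelSpec,
    StageThTable,
    c_index_evaluation,
    compare_with_without_th,
    harrell_c_index,
    km_logrank,
    linear_by_linear_trend,
    stratified_feature_analysis,
)


def expand_table(table):
    """Patient-level stage scores and high-TH indicators (oracle helper)."""
    scores, ind = [], []
    for s, (n, h) in enumerate(zip(table.n_per_stage, table.n_high_th), start=1):
        scores += [s] * n
        ind += [1] * h + [0] * (n - h)
    return np.array(scores, float), np.array(ind, float)


def brute_force_c_index(time, event, risk):
    """Concordant-pair fraction over evaluable pairs (Harrell's C oracle)."""
    time, event, risk = map(np.asarray, (time, event, risk))
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            first, second = (i, j) if time[i] < time[j] else (j, i)
            if not event[first]:
                continue  # pair not evaluable: earlier subject censored
            den += 1
            if risk[first] > risk[second]:
                num += 1
            elif risk[first] == risk[second]:
                num += 0.5
    return num / den


def welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def synth_clinical(n, rng, beta_th=math.log(2), beta_feat=math.log(2), base=1 / 24):
    """Clinical-only cohort with proportional hazards on TH and one feature."""
    th = rng.random(n) < 0.5
    feat = rng.random(n) < 0.5
    rate = base * np.exp(beta_th * th + beta_feat * feat)
    t_event = rng.exponential(1 / rate)
    t_cens = rng.exponential(1 / (rate * 0.4))
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": t_event <= t_cens,
            "th_group": np.where(th, "high", "low"),
            "feat": feat,
        }
    )


class TestTrendTest:
    def test_reference_stage_table(self):
        """Stage totals with high-TH counts (4, 13, 56, 79) give p near 0.046."""
        table = StageThTable(("I", "II", "III", "IV"), (10, 30, 125, 139), (4, 13, 56, 79))
        res = linear_by_linear_trend(table)
        assert res.pvalue == pytest.approx(0.046, abs=0.002)

    def test_matches_patient_level_correlation(self):
        table = StageThTable(("I", "II", "III"), (12, 20, 18), (3, 9, 13))
        res = linear_by_linear_trend(table)
        scores, ind = expand_table(table)
        r = np.corrcoef(scores, ind)[0, 1]
        assert res.statistic == pytest.approx((len(scores) - 1) * r**2, abs=1e-12)
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_no_trend_gives_p_one(self):
        table = StageThTable(("I", "II"), (10, 20), (5, 10))
        res = linear_by_linear_trend(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_count_scaling_behaviour(self):
        """r is count-scale invariant; M^2 scales as (kn - 1)/(n - 1)."""
        base = StageThTable(("I", "II", "III"), (10, 10, 10), (2, 5, 8))
        scaled = StageThTable(("I", "II", "III"), (30, 30, 30), (6, 15, 24))
        r1, r3 = linear_by_linear_trend(base), linear_by_linear_trend(scaled)
        assert r3.r == pytest.approx(r1.r, abs=1e-12)
        n = base.n
        assert r3.statistic == pytest.approx(r1.statistic * (3 * n - 1) / (n - 1), abs=1e-9)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            StageThTable(("I",), (10,), (5,))
        with pytest.raises(ValueError):
            StageThTable(("I", "II"), (10, 0), (5, 0))
        with pytest.raises(ValueError):
            StageThTable(("I", "II"), (10, 10), (11, 0))


class TestKaplanMeier:
    def test_textbook_product_limit(self):
        """Six subjects with two censorings, hand-computed step values."""
        time = [1, 2, 3, 4, 5, 6]
        event = [True, False, True, True, False, True]
        res = km_logrank(time + time, event + event, ["a"] * 6 + ["b"] * 6)
        curve = res.curves["a"].set_index("time")["survival"]
        assert curve.loc[1] == pytest.approx(5 / 6)
        assert curve.loc[3] == pytest.approx(5 / 6 * 3 / 4)
        assert curve.loc[4] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert curve.loc[6] == pytest.approx(0.0)

    def test_identical_groups_p_one(self):
        time = [3.0, 5.0, 7.0, 11.0]
        event = [True, True, False, True]
        res = km_logrank(time + time, event + event, ["a"] * 4 + ["b"] * 4)
        assert res.pvalue == pytest.approx(1.0)

    def test_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(4)
        df = synth_clinical(80, rng)
        res = km_logrank(df.time, df.event, df.th_group)
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_power_under_hazard_ratio_two(self):
        """HR 2 between TH groups at n=304 rejects in most replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            df = synth_clinical(304, rng, beta_th=math.log(2), beta_feat=0.0)
            hits += km_logrank(df.time, df.event, df.th_group).pvalue < 0.05
        assert hits >= 80

    def test_degenerate_no_events_flagged(self):
        res = km_logrank([1.0, 2.0, 3.0, 4.0], [False] * 4, ["a", "a", "b", "b"])
        assert math.isnan(res.pvalue)
        assert res.warnings

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_logrank([0.0, 1.0], [True, True], ["a", "b"])
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [True, True], ["a", "a"])


class TestStratifiedAnalysis:
    def test_extreme_group_comparison_beats_marginals(self):
        """Additive hazards: the extreme-strata contrast is usually sharper."""
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(100):
            df = synth_clinical(200, rng)
            strat = stratified_feature_analysis(df, "feat")
            p_th = km_logrank(df.time, df.event, df.th_group).pvalue
            p_feat = km_logrank(df.time, df.event,
                                np.where(df.feat, "pos", "neg")).pvalue
            wins += strat.pvalue < min(p_th, p_feat)
        assert wins >= 70

    def test_four_curves_present(self):
        rng = np.random.default_rng(7)
        df = synth_clinical(120, rng)
        res = stratified_feature_analysis(df, "feat")
        assert len(res.curves) == 4
        assert res.evaluable

    def test_constant_feature_reduces_to_th_comparison(self):
        rng = np.random.default_rng(8)
        df = synth_clinical(100, rng)
        df["feat"] = True
        res = stratified_feature_analysis(df, "feat")
        ref = km_logrank(df.time, df.event, df.th_group)
        assert res.evaluable
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_missing_values_excluded_and_counted(self):
        rng = np.random.default_rng(9)
        df = synth_clinical(60, rng)
        df["feat"] = df["feat"].astype(object)
        df.loc[:4, "feat"] = np.nan
        res = stratified_feature_analysis(df, "feat")
        assert res.n_excluded_missing == 5

    def test_small_strata_warn(self):
        rng = np.random.default_rng(10)
        df = synth_clinical(14, rng)
        res = stratified_feature_analysis(df, "feat")
        if res.evaluable:
            assert res.warnings  # low-power note on at least one stratum


class TestCIndex:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n = 25
        risk = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(risk))
        event = rng.random(n) < 0.8
        assert harrell_c_index(time, event, risk) == pytest.approx(
            brute_force_c_index(time, event, risk), abs=1e-12
        )

    def test_strong_binary_covariate_group_concordance(self):
        """No censoring: C equals the brute-force concordant fraction."""
        rng = np.random.default_rng(12)
        group = np.repeat([0.0, 1.0], 10)
        time = np.where(group > 0, rng.exponential(1.0, 20), rng.exponential(10.0, 20))
        event = np.ones(20, bool)
        c = harrell_c_index(time, event, group)
        assert c == pytest.approx(brute_force_c_index(time, event, group), abs=1e-12)
        # balanced binary risk: within-group pairs count 1/2, capping C near 0.76
        assert c > 0.7

    def test_null_covariate_concordance_half(self):
        rng = np.random.default_rng(13)
        n = 200
        df = pd.DataFrame(
            {
                "time": rng.exponential(10.0, n),
                "event": rng.random(n) < 0.7,
                "noise": (rng.random(n) < 0.5).astype(float),
            }
        )
        spec = RiskModelSpec(feature_sets={"noise": ["noise"]}, iterations=60,
                             subsample_fraction=0.8, seed=1)
        out = c_index_evaluation(df, spec)
        assert float(out["noise"].mean()) == pytest.approx(0.5, abs=0.05)

    def test_missing_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [True, True]})
        spec = RiskModelSpec(feature_sets={"bad": ["nope"]}, iterations=1)
        with pytest.raises(ValueError):
            c_index_evaluation(df, spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RiskModelSpec(feature_sets={}, iterations=0)
        with pytest.raises(ValueError):
            RiskModelSpec(feature_sets={}, subsample_fraction=1.5)


class TestWelchComparison:
    def test_identical_vectors(self):
        v = [0.6, 0.61, 0.62, 0.63]
        res = compare_with_without_th(v, v)
        assert res.mean_difference == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_constant_equal_vectors_flagged(self):
        res = compare_with_without_th([0.6, 0.6], [0.6, 0.6])
        assert res.flagged and res.pvalue == 1.0

    def test_separated_vectors(self):
        rng = np.random.default_rng(14)
        a = 0.9 + rng.normal(0, 1e-4, 30)
        b = 0.5 + rng.normal(0, 1e-4, 30)
        assert compare_with_without_th(a, b).pvalue < 1e-30

    def test_matches_textbook_welch_formula(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0.65, 0.02, 10), rng.normal(0.60, 0.03, 10)
        res = compare_with_without_th(a, b)
        t, df = welch_t(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-6)
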