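"""Exact 2x2 inference, rank tests, Cox/KM estimation and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom

from mpnstkit.clinstats import (apply_administrative_censoring, combined_strata,
                                cox_ph, dichotomize_burden, fisher_exact_2x2,
                                km_curve, spearman_bh, wilcoxon_rank_sum)
from mpnstkit.errors import ArgumentError, DataError


def enumeration_fisher_p(table) -> float:
    """Independent oracle: sum of hypergeometric probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    M, n, N = a + b + c + d, a + c, a + b
    lo, hi = max(0, N - (M - n)), min(n, N)
    probs = hypergeom.pmf(np.arange(lo, hi + 1), M, n, N)
    p_obs = hypergeom.pmf(a, M, n, N)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_reproduces_published_subtype_by_sex_statistics(self):
        res = fisher_exact_2x2([[15, 14], [13, 22]])
        assert round(res.or_cmle, 1) == 1.8
        assert round(res.ci_low, 1) == 0.6
        assert round(res.p, 1) == 0.3

    def test_one_sided_infinite_odds_ratio_with_finite_lower_bound(self):
        res = fisher_exact_2x2([[5, 0], [23, 36]])
        assert np.isinf(res.or_cmle) and np.isinf(res.ci_high)
        assert round(res.ci_low, 1) == 1.3
        assert round(res.p, 2) == 0.01

    def test_balanced_table_is_null(self):
        res = fisher_exact_2x2([[1, 1], [1, 1]])
        assert res.or_cmle == pytest.approx(1.0, abs=1e-6)
        assert res.p == 1.0

    def test_conditional_mle_differs_from_sample_or(self):
        res = fisher_exact_2x2([[17, 14], [10, 22]])
        assert res.or_sample == pytest.approx(17 * 22 / (14 * 10))
        assert round(res.or_cmle, 1) == 2.6  # shrunk relative to 2.67

    def test_ci_brackets_estimate(self):
        res = fisher_exact_2x2([[11, 21], [17, 15]])
        assert res.ci_low <= res.or_cmle <= res.ci_high

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_p_matches_enumeration_oracle(self, a, b, c, d):
        t = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            with pytest.raises(DataError):
                fisher_exact_2x2(t)
        else:
            assert fisher_exact_2x2(t).p == pytest.approx(enumeration_fisher_p(t),
                                                          abs=1e-10)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestWilcoxon:
    def test_extreme_ranking_exact_p(self):
        # all of x below all of y: 2 of C(6,3)=20 orderings are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ArgumentError):
            wilcoxon_rank_sum([], [1.0])

    def test_large_sample_null_uniformity(self):
        rng = np.random.default_rng(0)
        ps = [wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
              for _ in range(400)]
        assert 0.02 <= np.mean(np.asarray(ps) < 0.05) <= 0.09


class TestSpearman:
    def test_monotone_and_antisymmetry(self):
        x = np.arange(10.0)
        y = x**2
        out = spearman_bh([(x, y), (x, -y)])
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[1, "rho"] == pytest.approx(-1.0)

    def test_constant_vector_recorded_missing(self):
        out = spearman_bh([(np.ones(5), np.arange(5.0))])
        assert np.isnan(out.loc[0, "rho"])

    def test_bh_applied_across_pairs(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.normal(size=20), rng.normal(size=20)) for _ in range(6)]
        out = spearman_bh(pairs)
        assert (out["fdr"] >= out["p"] - 1e-12).all()


def brute_force_cox_coef(times, events, x) -> float:
    """1-D partial-likelihood maximiser by golden-section (no ties)."""
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    order = np.argsort(times)

    def neg_pl(beta):
        ll = 0.0
        for pos in range(len(times)):
            i = order[pos]
            if events[i]:
                risk = order[pos:]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    return float(minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10}).x)


class TestCox:
    def test_coefficient_matches_partial_likelihood_oracle(self):
        # alternating covariate keeps the partial likelihood maximiser finite
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
                            "x": [1.0, 0.0, 1.0, 0.0]})
        res = cox_ph(rec, ["x"])
        oracle = brute_force_cox_coef(rec["time"], rec["event"].to_numpy(), rec["x"])
        assert res.table.loc["x", "coef"] == pytest.approx(oracle, abs=1e-6)

    def test_recovers_simulated_hazard_ratio(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2.0) * x)))
        c = rng.uniform(0, 30, n)
        rec = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int),
                            "x": x})
        assert 1.8 <= cox_ph(rec, ["x"]).hr("x") <= 2.2

    def test_constant_covariate_and_no_events_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "x": [1.0, 1.0]})
        with pytest.raises(DataError):
            cox_ph(rec, ["x"])
        rec2 = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(DataError):
            cox_ph(rec2, ["x"])


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        rec = pd.DataFrame({"sample": ["a", "b", "c"], "time": [1.0, 2.0, 3.0],
                            "event": [1, 1, 1], "grp": ["g"] * 3})
        curves, _ = km_curve(rec, "grp")
        c = curves["g"]
        assert c.survival_at(1.0) == pytest.approx(2 / 3)
        assert c.survival_at(2.0) == pytest.approx(1 / 3)
        assert c.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        rec = pd.DataFrame({"sample": list("abc"), "time": [1.0, 2.0, 3.0],
                            "event": [0, 0, 0], "grp": ["g"] * 3})
        curves, _ = km_curve(rec, "grp")
        assert np.allclose(curves["g"].survival, 1.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(2.0, size=40)
        rec = pd.DataFrame({"sample": [f"s{i}" for i in range(40)], "time": times,
                            "event": 1, "grp": "g"})
        curves, _ = km_curve(rec, "grp")
        c = curves["g"]
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert c.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-9)

    def test_two_group_hazard_ratio_recovery(self):
        # averaged over a few replicates to control Monte-Carlo error
        hrs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n = 500
            grp = np.array(["lo"] * (n // 2) + ["hi"] * (n // 2))
            rate = np.where(grp == "hi", 0.3 * 3.0, 0.3)
            t = rng.exponential(1 / rate)
            rec = pd.DataFrame({"sample": [f"s{i}" for i in range(n)],
                                "time": np.minimum(t, 10.0),
                                "event": (t <= 10.0).astype(int), "grp": grp})
            _, pairs = km_curve(rec, "grp")
            hr = pairs.iloc[0]["hr_b_vs_a"]
            hrs.append(hr if pairs.iloc[0]["group_b"] == "hi" else 1 / hr)
        assert 2.4 <= np.mean(hrs) <= 3.75


class TestDichotomization:
    def test_recovers_planted_hazard_jump(self):
        rng = np.random.default_rng(4)
        n = 300
        burden = rng.uniform(0, 60, n)
        rate = np.where(burden > 30, 1.0, 0.15)
        t = rng.exponential(1 / rate)
        rec = pd.DataFrame({"sample": [f"s{i}" for i in range(n)],
                            "time": np.minimum(t, 5.0), "event": (t <= 5.0).astype(int)})
        burdens = pd.Series(burden, index=rec["sample"], name="burden")
        out = dichotomize_burden(burdens, rec, method="maxstat")
        assert 25.0 <= out["threshold"] <= 35.0

    def test_fixed_threshold_validation(self):
        rec = pd.DataFrame({"sample": [f"s{i}" for i in range(12)],
                            "time": np.arange(1, 13, dtype=float), "event": 1})
        burdens = pd.Series(np.linspace(10, 20, 12), index=rec["sample"])
        with pytest.raises(DataError):
            dichotomize_burden(burdens, rec, method="fixed", threshold=5.0)
        out = dichotomize_burden(burdens, rec, method="fixed", threshold=15.0)
        assert set(out["labels"].unique()) == {"high", "low"}


class TestCombinedStrata:
    def test_toy_bookkeeping(self):
        samples = [f"s{i}" for i in range(8)]
        loss = pd.Series(["low"] * 3 + ["high"] * 5, index=samples)
        loh = pd.Series(["low"] * 3 + ["low", "low", "high", "high", "high"],
                        index=samples)
        rec = pd.DataFrame({"sample": samples, "time": np.arange(1.0, 9.0),
                            "event": [1, 0, 1, 1, 0, 1, 1, 1]})
        out = combined_strata(loss, loh, rec)
        sizes = out["strata_sizes"]
        assert sizes["low/low"] == 3 and sum(sizes.values()) == 8
        contrast = out["low_vs_rest"]
        assert set(contrast[["group_a", "group_b"]].iloc[0]) == {
            "both_low", "loss_or_loh_high"}

    def test_single_stratum_rejected(self):
        samples = [f"s{i}" for i in range(4)]
        loss = pd.Series("low", index=samples)
        loh = pd.Series("low", index=samples)
        rec = pd.DataFrame({"sample": samples, "time": [1.0, 2, 3, 4], "event": 1})
        with pytest.raises(DataError):
            combined_strata(loss, loh, rec)


def test_administrative_censoring_window():
    rec = pd.DataFrame({"sample": ["a", "b"], "time": [6.2, 3.0], "event": [1, 1]})
    out = apply_administrative_censoring(rec, horizon=5.0)
    assert out.loc[0, "time"] == 5.0 and out.loc[0, "event"] == 0
    assert out.loc[1, "time"] == 3.0 and out.loc[1, "event"] == 1
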