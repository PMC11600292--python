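"""Kaplan-Meier, log-rank, Cox and maximally selected cutpoints, checked
against hand calculations, brute-force oracles and lifelines."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circmm.survanalysis import (
    ConvergenceError,
    CutpointResult,
    SurvivalData,
    cox_univariate,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    survival_screen,
)
from conftest import random_survival


def naive_logrank_chi2(time, event, group1):
    """Independent from-scratch log-rank statistic: python loop over event times."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    group1 = np.asarray(group1, bool)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e, var)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        d = SurvivalData(np.array([5.0, 7.0, 9.0]), np.array([0, 0, 0]))
        km = km_estimate(d)
        assert km.survival_at(100.0) == 1.0

    def test_three_distinct_events_step_thirds(self):
        d = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        km = km_estimate(d)
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_between_events_product_limit(self):
        d = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        km = km_estimate(d)
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData(np.array([0.0, 1.0]), np.array([1, 1]))

    def test_curve_is_monotone_and_matches_uncensored_closed_form(self):
        rng = np.random.default_rng(0)
        time, event = random_survival(rng, 50)
        km = km_estimate(SurvivalData(time, event))
        assert (np.diff(km.survival) <= 1e-12).all()
        all_events = SurvivalData(time, np.ones_like(event))
        km2 = km_estimate(all_events)
        assert km2.survival[-1] == pytest.approx(0.0)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        time, event = random_survival(rng, 80)
        km = km_estimate(SurvivalData(time, event))
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        assert np.allclose(km.survival, theirs, atol=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        d = SurvivalData(time, event)
        res = logrank_test(d, ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_symmetry_and_time_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        time, event = random_survival(rng, 30)
        labels = rng.integers(0, 2, 30)
        d = SurvivalData(time, event)
        res = logrank_test(d, labels)
        res_flip = logrank_test(d, 1 - labels)
        res_scaled = logrank_test(SurvivalData(time * 12.0, event), labels)
        assert res.statistic == pytest.approx(res_flip.statistic)
        assert res.statistic == pytest.approx(res_scaled.statistic)

    def test_matches_independent_loop_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            time, event = random_survival(rng, 25)
            g = rng.integers(0, 2, 25).astype(bool)
            if g.all() or not g.any():
                continue
            d = SurvivalData(time, event)
            res = logrank_test(d, np.where(g, "x", "y"))
            oe, var = naive_logrank_chi2(time, event, g)  # chi2 is symmetric in the group choice
            assert res.statistic == pytest.approx(oe**2 / var, rel=1e-10)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        time, event = random_survival(rng, 60)
        g = rng.integers(0, 2, 60).astype(bool)
        res = logrank_test(SurvivalData(time, event), g)
        theirs = ll_logrank(time[g], time[~g], event[g], event[~g])
        assert res.p_value == pytest.approx(theirs.p_value, rel=1e-6)

    def test_eight_subject_permutation_oracle(self):
        """At n=8 the chi-square p tracks the exact permutation distribution on
        average; per-instance gaps are bounded by the approximation's known
        anti-conservatism against a 70-atom discrete null."""
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        diffs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            time, event = random_survival(rng, 8)
            res = logrank_test(SurvivalData(time, event), g)
            chi2s = []
            for idx in itertools.combinations(range(8), 4):
                gg = np.zeros(8, bool)
                gg[list(idx)] = True
                oe, var = naive_logrank_chi2(time, event, gg)
                chi2s.append(oe**2 / var if var > 0 else 0.0)
            p_perm = np.mean([c >= res.statistic - 1e-12 for c in chi2s])
            diffs.append(abs(res.p_value - p_perm))
        assert np.mean(diffs) <= 0.05
        assert max(diffs) <= 0.15

    def test_three_group_version_reduces_to_chi2_df2(self):
        rng = np.random.default_rng(7)
        time, event = random_survival(rng, 45)
        labels = rng.integers(0, 3, 45)
        res = logrank_test(SurvivalData(time, event), labels)
        assert res.method == "logrank_3group"
        assert 0.0 <= res.p_value <= 1.0

    def test_zero_events_rejected(self):
        d = SurvivalData(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError):
            logrank_test(d, ["a", "b"])


def grid_search_cox_beta(time, event, x, lo=-3.0, hi=3.0, step=1e-4):
    """Independent grid maximizer of the Breslow partial likelihood."""
    time, event, x = map(np.asarray, (time, event, x))

    def loglik(beta):
        ll = 0.0
        for t in sorted(set(time[event == 1])):
            deaths = (time == t) & (event == 1)
            risk = time >= t
            ll += beta * x[deaths].sum() - deaths.sum() * math.log(
                np.exp(beta * x[risk]).sum())
        return ll

    grid = np.arange(lo, hi + step, step)
    values = [loglik(b) for b in grid]
    return grid[int(np.argmax(values))]


class TestCox:
    def test_identical_event_patterns_hr_one(self):
        time = np.tile([2.0, 5.0, 9.0, 14.0], 2)
        event = np.tile([1, 1, 0, 1], 2)
        x = np.repeat([0.0, 1.0], 4)
        fit = cox_univariate(SurvivalData(time, event), x)
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_six_subject_grid_search_oracle(self):
        time = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_univariate(SurvivalData(time, event), x)
        oracle = grid_search_cox_beta(time, event, x)
        assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_parameter_recovery_on_simulated_hazards(self):
        rng = np.random.default_rng(11)
        betas = []
        for _ in range(5):
            x = rng.normal(size=500)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
            t = np.maximum(t, 1e-3)
            event = (t < 60).astype(int)
            time = np.minimum(t, 60)
            betas.append(cox_univariate(SurvivalData(time, event), x).beta)
        assert np.mean(betas) == pytest.approx(0.7, abs=0.1)

    def test_efron_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        time, event = random_survival(rng, 70)
        x = rng.normal(size=70)
        fit = cox_univariate(SurvivalData(time, event), x, ties="efron")
        frame = pd.DataFrame({"T": time, "E": event, "x": x})
        cph = lifelines.CoxPHFitter().fit(frame, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-3)

    def test_constant_covariate_rejected(self):
        d = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(d, np.ones(3))

    def test_perfect_separation_raises_convergence_error(self):
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError):
            cox_univariate(SurvivalData(time, event), x)


def exhaustive_cutpoint_oracle(time, event, expr, minprop=0.2):
    """Naive scan over admissible midpoints using the loop log-rank oracle."""
    expr = np.asarray(expr, float)
    n = expr.size
    distinct = np.unique(expr)
    best = None
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        high = expr > cut
        if min(high.sum(), (~high).sum()) < math.ceil(minprop * n):
            continue
        oe, var = naive_logrank_chi2(time, event, high)
        z = abs(oe) / math.sqrt(var) if var > 0 else 0.0
        if best is None or z > best[1] + 1e-12:
            best = (cut, z)
    return best


class TestOptimalCutpoint:
    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            n = int(rng.integers(12, 40))
            time, event = random_survival(rng, n)
            expr = np.round(rng.normal(size=n), 2)
            if np.unique(expr).size < 2:
                continue
            try:
                res = optimal_cutpoint(SurvivalData(time, event), expr)
            except ValueError:
                assert exhaustive_cutpoint_oracle(time, event, expr) is None
                continue
            cut, z = exhaustive_cutpoint_oracle(time, event, expr)
            assert res.cutpoint == pytest.approx(cut, abs=1e-12)
            assert abs(res.statistic) == pytest.approx(z, rel=1e-9)

    def test_minprop_guarantees_group_sizes(self):
        rng = np.random.default_rng(21)
        time, event = random_survival(rng, 10)
        expr = np.arange(10, dtype=float)
        res = optimal_cutpoint(SurvivalData(time, event), expr, minprop=0.2)
        assert min(res.n_high, res.n_low) >= 2

    def test_increasing_minprop_never_increases_statistic(self):
        rng = np.random.default_rng(22)
        time, event = random_survival(rng, 40)
        expr = rng.normal(size=40)
        d = SurvivalData(time, event)
        z_small = abs(optimal_cutpoint(d, expr, minprop=0.1).statistic)
        z_big = abs(optimal_cutpoint(d, expr, minprop=0.4).statistic)
        assert z_big <= z_small + 1e-12

    def test_constant_expression_rejected(self):
        d = SurvivalData(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), np.array([1, 1, 1, 0, 1]))
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(d, np.ones(5))


class TestSurvivalScreen:
    def make_screen_inputs(self, rng, n=40, n_feat=12):
        time, event = random_survival(rng, n)
        cols = [f"s{i}" for i in range(n)]
        counts = pd.DataFrame(rng.poisson(40, size=(n_feat, n)),
                              index=[f"f{i}" for i in range(n_feat)], columns=cols)
        s = pd.Series(1.0, index=cols)
        return counts, s, SurvivalData(time, event, sample_ids=cols)

    def test_flat_survival_reports_p_one_everywhere(self):
        rng = np.random.default_rng(30)
        counts, s, _ = self.make_screen_inputs(rng)
        n = counts.shape[1]
        # every subject identical: any split gives a null log-rank
        d = SurvivalData(np.full(n, 12.0), np.ones(n, int), sample_ids=list(counts.columns))
        out = survival_screen(counts, s, d, top_k=5)
        assert np.allclose(out.table["p"].dropna(), 1.0)

    def test_planted_prognostic_feature_wins_the_screen(self):
        rng = np.random.default_rng(31)
        n = 100
        sev = rng.normal(size=n)
        t = np.maximum(rng.exponential(1.0 / (0.02 * np.exp(1.0 * sev))), 1e-3)
        event = (t < 120).astype(int)
        time = np.minimum(t, 120)
        cols = [f"s{i}" for i in range(n)]
        counts = pd.DataFrame(rng.poisson(50, size=(20, n)), columns=cols,
                              index=[f"null{i}" for i in range(20)])
        planted = np.maximum(rng.poisson(50 * np.exp(0.8 * sev)), 0)
        counts.loc["planted"] = planted
        s = pd.Series(1.0, index=cols)
        d = SurvivalData(time, event, sample_ids=cols)
        out = survival_screen(counts, s, d, top_k=21)
        best = out.table.loc[out.table["p"].idxmin(), "feature_id"]
        assert best == "planted"
        assert out.table.loc["planted", "direction"] == "favourable_low"

    def test_top_k_clipped_with_warning(self, caplog):
        rng = np.random.default_rng(32)
        counts, s, d = self.make_screen_inputs(rng, n_feat=4)
        with caplog.at_level("WARNING"):
            out = survival_screen(counts, s, d, top_k=100)
        assert len(out.table) == 4
        assert "top_k" in caplog.text

    def test_summary_counts_match_table(self):
        rng = np.random.default_rng(33)
        counts, s, d = self.make_screen_inputs(rng)
        out = survival_screen(counts, s, d, top_k=12)
        sig = out.table[out.table["p"] < 0.05]
        assert out.n_significant == len(sig)
        assert out.n_favourable_high == (sig["direction"] == "favourable_high").sum()
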