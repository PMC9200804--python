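"""Staging rules, evolving biomarkers, and the survival stack."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from smmsubtypes.outcomes import (
    biomarker_association,
    c_index,
    compare_models,
    cox_fit,
    detect_evolving_biomarkers,
    km_fit,
    logrank_test,
    stage_20_2_20,
)


class TestStaging:
    @pytest.mark.parametrize(
        "inputs,stage,count",
        [
            ((2.5, 25, 15), "high", 2),
            ((1.0, 10, 10), "low", 0),
            ((2.0, 10, 10), "low", 0),     # 2.0 is not >2: strict boundary
            ((2.0, 20, 20), "low", 0),     # all three at the boundary
            ((2.1, 10, 10), "intermediate", 1),
            ((2.1, 21, 21), "high", 3),
        ],
    )
    def test_2_2_20_rules(self, inputs, stage, count):
        assert stage_20_2_20(*inputs) == (stage, count)

    def test_missing_input_gives_missing_stage(self):
        assert stage_20_2_20(None, 10, 10) == ("missing", None)
        assert stage_20_2_20(1.0, float("nan"), 10) == ("missing", None)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            stage_20_2_20(-1.0, 10, 10)


class TestEvolvingBiomarkers:
    def test_emp_requires_both_thresholds(self):
        # +60% and +0.6 g/dL at month 10: evolving
        assert detect_evolving_biomarkers([(0, 1.0), (10, 1.6)], [])[0] is True
        # +30% but only +0.3 g/dL: not evolving
        assert detect_evolving_biomarkers([(0, 1.0), (6, 1.3)], [])[0] is False
        # +0.6 g/dL but only +15%: not evolving
        assert detect_evolving_biomarkers([(0, 4.0), (9, 4.6)], [])[0] is False

    def test_ehb_absolute_drop(self):
        emp, ehb = detect_evolving_biomarkers([], [(0, 12.0), (8, 11.4)])
        assert ehb is True
        assert detect_evolving_biomarkers([], [(0, 12.0), (8, 11.6)])[1] is False

    def test_window_is_within_12_months(self):
        # the rise happens only after month 12: not evolving
        assert detect_evolving_biomarkers([(0, 1.0), (14, 2.0)], [])[0] is False
        # exactly at month 12 counts
        assert detect_evolving_biomarkers([(0, 1.0), (12, 1.6)], [])[0] is True

    def test_series_without_baseline_not_evaluated(self):
        assert detect_evolving_biomarkers([(3, 1.0), (6, 2.0)], []) == (False, False)
        assert detect_evolving_biomarkers([], []) == (False, False)

    def test_zero_baseline_uses_absolute_rule(self, caplog):
        with caplog.at_level("WARNING"):
            emp, _ = detect_evolving_biomarkers([(0, 0.0), (6, 0.6)], [])
        assert emp is True


class TestKaplanMeier:
    def test_empirical_steps_and_median(self):
        fit = km_fit([1, 2, 3, 4, 5], [True] * 5)
        curve = fit.curves["all"]["survival"]
        np.testing.assert_allclose(
            curve.loc[[1, 2, 3, 4, 5]].to_numpy(), [0.8, 0.6, 0.4, 0.2, 0.0]
        )
        assert fit.medians["all"] == 3

    def test_all_censored_median_undefined(self):
        fit = km_fit([1, 2, 3], [False] * 3)
        assert np.isinf(fit.medians["all"])
        assert (fit.curves["all"]["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, size=40)
        fit = km_fit(t, [True] * 40)
        curve = fit.curves["all"]["survival"]
        for ti in t:
            assert curve.loc[ti] == pytest.approx((t > ti).mean())

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 1.0], [True, True])

    def test_reverse_km_followup(self):
        # all events -> follow-up (censoring) distribution is undefined (inf)
        fit = km_fit([1, 2, 3, 4], [True] * 4)
        assert np.isinf(fit.reverse_km_median_followup)
        fit = km_fit([1, 2, 3, 4], [False] * 4)
        assert fit.reverse_km_median_followup == 2


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        chi2, p = logrank_test(t + t, [True] * 8, ["a"] * 4 + ["b"] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # groups (1,2) vs (3,4), all events: O-E = 7/6, V = 17/36
        chi2, p = logrank_test([1, 2, 3, 4], [True] * 4, ["a", "a", "b", "b"])
        assert chi2 == pytest.approx(49 / 17, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])

    def test_label_swap_invariance(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [True] * 6
        g = ["a", "b", "a", "b", "a", "b"]
        swapped = ["b" if x == "a" else "a" for x in g]
        assert logrank_test(t, e, g)[0] == pytest.approx(logrank_test(t, e, swapped)[0])


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(5, n)
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        hr = fit.summary.loc[0, "HR"]
        assert 0.8 < hr < 1.25

    def test_two_group_exponential_recovery(self):
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(np.where(x == 1, 1.0, 4.5))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        assert fit.summary.loc[0, "coef"] == pytest.approx(np.log(4.5), abs=0.2)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1, 1, 1]}), [1, 2, 3], [True] * 3)

    def test_more_params_than_events_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "y": [1, 0, 0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, [1, 2, 3, 4], [True, False, False, False])


class TestCompareModels:
    @staticmethod
    def _sim(seed, n=80, signal=False):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        z = rng.integers(0, 2, n).astype(float)
        scale = np.exp(-0.8 * x) if signal else np.ones(n)
        t = rng.exponential(scale)
        cov = pd.DataFrame({"x": x, "z": z})
        return cov, t, np.ones(n, bool)

    def test_identical_models_degenerate(self):
        cov, t, e = self._sim(0)
        base = cox_fit(cov[["x"]], t, e)
        assert compare_models(base, base) == {"lr_chi2": 0.0, "df": 0, "p": 1.0}

    def test_non_nested_rejected(self):
        cov, t, e = self._sim(0)
        a = cox_fit(cov[["x"]], t, e)
        b = cox_fit(cov[["z"]], t, e)
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)

    def test_noise_covariate_lr_p_uniform(self):
        pvals = []
        for seed in range(500):
            cov, t, e = self._sim(seed, n=60, signal=True)
            base = cox_fit(cov[["x"]], t, e)
            ext = cox_fit(cov, t, e)
            pvals.append(compare_models(base, ext)["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_genetic_signal_raises_c_index(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            stage = rng.integers(0, 2, n).astype(float)
            genetic = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(np.exp(-0.5 * stage - 1.0 * genetic))
            cov = pd.DataFrame({"stage": stage, "genetic": genetic})
            e = np.ones(n, bool)
            base = cox_fit(cov[["stage"]], t, e)
            ext = cox_fit(cov, t, e)
            comp = compare_models(base, ext, cov, t, e)
            wins += comp["c_extended"] > comp["c_base"]
        assert wins >= 9


class TestCIndex:
    def test_perfect_and_reversed_ordering(self):
        assert c_index([3, 2, 1], [1, 2, 3], [True] * 3)[0] == 1.0
        assert c_index([1, 2, 3], [1, 2, 3], [True] * 3)[0] == 0.0

    def test_tie_contributes_half(self):
        c, lo, hi = c_index([2, 2, 1], [1, 2, 3], [True] * 3)
        assert c == pytest.approx(2.5 / 3)
        assert 0 <= lo <= c <= hi <= 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        t = rng.exponential(1, 50)
        e = rng.random(50) < 0.7
        c1 = c_index(s, t, e)[0]
        c2 = c_index(np.exp(2 * s) + 5, t, e)[0]
        assert c1 == pytest.approx(c2)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        s = rng.normal(size=80)
        t = rng.exponential(1, 80)
        e = rng.random(80) < 0.6
        ours = c_index(s, t, e)[0]
        # lifelines orders by predicted survival time (higher = later event)
        theirs = concordance_index(t, -s, e)
        assert ours == pytest.approx(theirs)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            c_index([1, 2], [5, 5], [False, False])


class TestBiomarkerAssociation:
    def test_cross_product_example(self):
        flags = [True] * 20 + [False] * 30 + [True] * 5 + [False] * 95
        groups = ["high"] * 50 + ["low"] * 100
        out = biomarker_association(flags, groups)
        assert out["odds_ratio"] == pytest.approx((20 * 95) / (30 * 5))
        assert 0 < out["p"] < 1

    def test_equal_proportions_null(self):
        flags = ([True] * 5 + [False] * 5) * 2
        groups = ["high"] * 10 + ["low"] * 10
        out = biomarker_association(flags, groups)
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_degenerate_flags_rejected(self):
        with pytest.raises(ValueError):
            biomarker_association([True] * 10, ["high"] * 5 + ["low"] * 5)

    def test_logistic_route_close_to_table(self):
        flags = [True] * 20 + [False] * 30 + [True] * 5 + [False] * 95
        groups = ["high"] * 50 + ["low"] * 100
        table = biomarker_association(flags, groups)
        logistic = biomarker_association(flags, groups, method="logistic")
        assert logistic["odds_ratio"] == pytest.approx(table["odds_ratio"], rel=1e-3)
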