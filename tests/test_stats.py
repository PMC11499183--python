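"""Accuracy metrics, agreement, logistic regression, group comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from qtaudit.stats import (
    ConfusionCounts,
    agreement,
    compare_groups,
    confusion,
    diagnostic_metrics,
    fit_logistic,
)

STUDY_COUNTS = ConfusionCounts(tp=25, fp=53, tn=485, fn=4)


class TestConfusion:
    def test_tabulates_categories(self):
        cats = ["TN"] * 485 + ["FN"] * 4 + ["FP"] * 53 + ["TP"] * 25
        c = confusion(cats)
        assert (c.tp, c.fp, c.tn, c.fn) == (25, 53, 485, 4)
        assert c.n == 567

    def test_all_tn(self):
        c = confusion(["TN"] * 7)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 7, 0)

    def test_one_of_each(self):
        c = confusion(["TP", "FP", "TN", "FN"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            confusion([])


class TestDiagnosticMetrics:
    def test_low_ppv_high_npv_pattern(self):
        # a screening pattern: most automated positives are unconfirmed,
        # automated negatives almost always confirmed
        rep = diagnostic_metrics(STUDY_COUNTS)
        assert round(100 * rep.ppv.estimate) == 32
        assert round(100 * rep.npv.estimate) == 99
        assert round(rep.cell_percent["fp"]) == 9
        assert round(rep.cell_percent["tp"], 1) == 4.4

    def test_perfect_classifier(self):
        rep = diagnostic_metrics(ConfusionCounts(10, 0, 10, 0))
        for m in (rep.ppv, rep.npv, rep.sensitivity, rep.specificity):
            assert m.estimate == pytest.approx(1.0)

    def test_zero_denominator_undefined_not_boundary(self):
        rep = diagnostic_metrics(ConfusionCounts(0, 0, 5, 5))
        assert np.isnan(rep.ppv.estimate)
        assert not np.isnan(rep.npv.estimate)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_wilson_ci_brackets_estimate(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        rep = diagnostic_metrics(ConfusionCounts(tp, fp, tn, fn))
        for m in (rep.ppv, rep.npv, rep.sensitivity, rep.specificity):
            if m.defined:
                assert 0.0 <= m.ci_low <= m.estimate <= m.ci_high <= 1.0


class TestAgreement:
    def test_identical_readings(self):
        x = [400.0, 410.0, 450.0, 500.0]
        flags = [False, False, False, True]
        res = agreement((x, x), (flags, flags))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.cohen_kappa == pytest.approx(1.0)

    def test_affine_invariance_of_r(self):
        x = np.array([400.0, 410.0, 450.0, 500.0, 380.0])
        res = agreement((x, 2 * x + 5), ([True, False] * 2 + [True],
                                         [True, False] * 2 + [True]))
        assert res.pearson_r == pytest.approx(1.0)

    def test_independent_flags_give_near_zero_kappa(self):
        rng = np.random.default_rng(8)
        n = 4000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.3
        x = rng.normal(400, 30, n)
        y = rng.normal(400, 30, n)
        res = agreement((x, y), (a, b))
        assert abs(res.cohen_kappa) < 0.05
        assert abs(res.pearson_r) < 0.05

    def test_zero_variance_r_undefined(self):
        res = agreement(([1.0, 1.0, 1.0], [2.0, 3.0, 4.0]),
                        ([True, False], [True, False]))
        assert np.isnan(res.pearson_r)


def _loglik(y, X, beta):
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _grid_mle(y, X, lo=-3.0, hi=3.0):
    """Independent oracle: nested grid search of the 2-parameter likelihood."""
    b0s = np.linspace(lo, hi, 41)
    b1s = np.linspace(lo, hi, 41)
    best = (0.0, 0.0)
    for _ in range(4):
        ll = np.array([[_loglik(y, X, np.array([b0, b1])) for b1 in b1s]
                       for b0 in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (b0s[i], b1s[j])
        w0 = (b0s[1] - b0s[0]) * 2
        w1 = (b1s[1] - b1s[0]) * 2
        b0s = np.linspace(best[0] - w0, best[0] + w0, 41)
        b1s = np.linspace(best[1] - w1, best[1] + w1, 41)
    return best


class TestFitLogistic:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.random(n) < 0.5
        eta = -1.0 + 0.8 * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        design = pd.DataFrame({"x": x.astype(float)})
        res = fit_logistic(design, y)
        X = np.column_stack([np.ones(n), x.astype(float)])
        b0, b1 = _grid_mle(y.astype(float), X)
        assert res.table.loc["const", "coef"] == pytest.approx(b0, abs=1e-3)
        assert res.table.loc["x", "coef"] == pytest.approx(b1, abs=1e-3)

    def test_null_covariates_cover_or_one(self):
        rng = np.random.default_rng(6)
        n = 5000
        design = pd.DataFrame({
            "a": (rng.random(n) < 0.4).astype(float),
            "b": rng.normal(0, 1, n),
        })
        y = rng.random(n) < 0.2
        res = fit_logistic(design, y)
        for name in ("a", "b"):
            lo, hi = res.ci(name)
            assert lo <= 1.0 <= hi

    def test_degenerate_outcome_rejected(self):
        design = pd.DataFrame({"x": np.arange(50, dtype=float)})
        with pytest.raises(ValueError):
            fit_logistic(design, np.ones(50, dtype=bool))

    def test_complete_separation_flagged(self):
        x = np.arange(40, dtype=float)
        y = x >= 20
        res = fit_logistic(pd.DataFrame({"x": x}), y)
        assert res.separation


class TestCompareGroups:
    def test_identical_samples_t_zero(self):
        v = list(np.r_[np.arange(10.0), np.arange(10.0)])
        g = ["a"] * 10 + ["b"] * 10
        res = compare_groups(v, g)
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_extreme_2x2_uses_fisher(self):
        v = [True] * 10 + [False] * 10
        g = ["a"] * 10 + ["b"] * 10
        res = compare_groups(v, g)
        assert res.test == "fisher"
        # oracle: exact hypergeometric tail for the (10,0 / 0,10) table
        expected = scipy.stats.fisher_exact([[10, 0], [0, 10]])[1]
        assert res.p_value == pytest.approx(expected)
        assert res.p_value < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])

    def test_type_one_error_calibrated(self):
        # 2000 null replicates of a two-sample t at nominal alpha = 0.05
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, size=(2000, 40))
        b = rng.normal(0, 1, size=(2000, 40))
        res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=True)
        # sanity-lock our wrapper to the vectorized computation on one case
        one = compare_groups(list(np.r_[a[0], b[0]]),
                             ["a"] * 40 + ["b"] * 40)
        assert one.p_value == pytest.approx(res.pvalue[0])
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.03 <= rate <= 0.07
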