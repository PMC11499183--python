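"""Diagnostic accuracy, agreement, and predictor analyses for paired calls.

Aggregates paired automated/manual long-QT calls into a 2x2 table, computes
sensitivity/specificity/PPV/NPV with Wilson score intervals, measures
continuous and categorical agreement (Pearson r, Cohen's kappa), fits a
multivariable logistic regression for predictors of false-positive calls,
and runs the usual two-group comparisons (Student's t, chi-square, Fisher's
exact when expected cells are small).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .qtc import PairedCall

CATEGORIES = ("TP", "FP", "TN", "FN")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricCI:
    """A proportion with its Wilson 95% interval (nan when undefined)."""

    estimate: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.estimate)


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    cell_percent: dict = field(default_factory=dict)
    counts: ConfusionCounts | None = None


def confusion(pairs: Iterable[PairedCall | str]) -> ConfusionCounts:
    """Count 2x2 categories from paired calls (or category strings)."""
    tallies = dict.fromkeys(CATEGORIES, 0)
    n = 0
    for p in pairs:
        cat = p if isinstance(p, str) else p.category
        if cat not in tallies:
            raise ValueError(f"unknown category {cat!r}")
        tallies[cat] += 1
        n += 1
    if n == 0:
        raise ValueError("no paired calls to tabulate")
    return ConfusionCounts(tp=tallies["TP"], fp=tallies["FP"],
                           tn=tallies["TN"], fn=tallies["FN"])


def _wilson(count: int, nobs: int) -> MetricCI:
    if nobs == 0:
        return MetricCI(float("nan"), float("nan"), float("nan"))
    est = count / nobs
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    # guard the float fuzz at the boundaries so the CI always brackets
    lo = min(max(float(lo), 0.0), est)
    hi = max(min(float(hi), 1.0), est)
    return MetricCI(est, lo, hi)


def diagnostic_metrics(counts: ConfusionCounts) -> AccuracyReport:
    """Sensitivity, specificity, PPV, NPV with Wilson 95% CIs.

    Metrics with a zero denominator are reported as undefined (nan), never
    as 0 or 1.  Cell percentages are shares of the total n.
    """
    n = counts.n
    if n < 1:
        raise ValueError("need at least one paired call")
    report = AccuracyReport(
        sensitivity=_wilson(counts.tp, counts.tp + counts.fn),
        specificity=_wilson(counts.tn, counts.tn + counts.fp),
        ppv=_wilson(counts.tp, counts.tp + counts.fp),
        npv=_wilson(counts.tn, counts.tn + counts.fn),
        cell_percent={
            "tp": 100.0 * counts.tp / n,
            "fp": 100.0 * counts.fp / n,
            "tn": 100.0 * counts.tn / n,
            "fn": 100.0 * counts.fn / n,
        },
        counts=counts,
    )
    return report


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    cohen_kappa: float


def agreement(
    qt_pairs: tuple[Sequence[float], Sequence[float]],
    lqt_pairs: tuple[Sequence[bool], Sequence[bool]],
) -> AgreementResult:
    """Continuous and categorical agreement between two readings.

    Pearson's r on the paired continuous values (undefined for zero
    variance); Cohen's kappa on the paired binary calls, with
    marginal-product expected agreement (undefined when expected agreement
    is 1).
    """
    x = np.asarray(qt_pairs[0], dtype=float)
    y = np.asarray(qt_pairs[1], dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired continuous values")
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(scipy.stats.pearsonr(x, y).statistic)

    a = np.asarray(lqt_pairs[0], dtype=bool)
    b = np.asarray(lqt_pairs[1], dtype=bool)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired binary calls")
    po = float(np.mean(a == b))
    pa1, pb1 = float(np.mean(a)), float(np.mean(b))
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    kappa = float("nan") if pe == 1.0 else (po - pe) / (1.0 - pe)
    return AgreementResult(pearson_r=r, cohen_kappa=kappa)


@dataclass
class RegressionResult:
    """Per-covariate coefficients, odds ratios, Wald 95% CIs and p-values."""

    table: pd.DataFrame  # index: covariate; cols: coef, se, or, or_low, or_high, p
    converged: bool
    separation: bool
    n: int

    def odds_ratio(self, name: str) -> float:
        return float(self.table.loc[name, "or"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["or_low"]), float(row["or_high"])


def fit_logistic(design: pd.DataFrame, outcome: Sequence[bool]) -> RegressionResult:
    """Multivariable logistic regression by maximum likelihood (IRLS/Newton).

    An intercept is added automatically.  Complete separation or failed
    convergence is flagged on the result rather than silently reported as
    valid estimates.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    if len(y) != len(X):
        raise ValueError("design and outcome length mismatch")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than covariates")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params = res.params
        bse = res.bse
        ci = res.conf_int()
        pvals = res.pvalues
    except Exception:
        nan = np.full(Xc.shape[1], np.nan)
        params = pd.Series(nan, index=Xc.columns)
        bse = pd.Series(nan, index=Xc.columns)
        ci = pd.DataFrame({0: nan, 1: nan}, index=Xc.columns)
        pvals = pd.Series(nan, index=Xc.columns)
        separation = True
    if not separation:
        big = (np.abs(params) > 15) | (np.asarray(bse) > 1e3)
        if bool(np.any(big)) or not np.all(np.isfinite(bse)):
            separation = True
    with np.errstate(over="ignore"):  # separated fits can overflow to inf
        table = pd.DataFrame({
            "coef": params,
            "se": bse,
            "or": np.exp(params),
            "or_low": np.exp(ci[0]),
            "or_high": np.exp(ci[1]),
            "p": pvals,
        })
    return RegressionResult(table=table, converged=converged,
                            separation=separation, n=len(y))


@dataclass(frozen=True)
class GroupTest:
    statistic: float
    p_value: float
    test: str  # t | chi2 | fisher


def compare_groups(values: Sequence, groups: Sequence) -> GroupTest:
    """Two-group comparison, choosing the test the data call for.

    Continuous values -> Student's two-sample t-test (pooled variance);
    categorical/binary values -> chi-square on the contingency table,
    switching to Fisher's exact test when any expected cell is below 5
    (2x2 tables only).
    """
    v = pd.Series(list(values))
    g = pd.Series(list(groups))
    levels = g.unique()
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    if v.dtype.kind == "f" or (v.dtype.kind in "iu" and v.nunique() > 5):
        a = v[g == levels[0]].astype(float)
        b = v[g == levels[1]].astype(float)
        res = scipy.stats.ttest_ind(a, b, equal_var=True)
        return GroupTest(float(res.statistic), float(res.pvalue), "t")
    table = pd.crosstab(v, g)
    chi2 = scipy.stats.chi2_contingency(table.values, correction=False)
    if table.shape == (2, 2) and chi2.expected_freq.min() <= 5:
        odds, p = scipy.stats.fisher_exact(table.values)
        return GroupTest(float(odds), float(p), "fisher")
    return GroupTest(float(chi2.statistic), float(chi2.pvalue), "chi2")
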