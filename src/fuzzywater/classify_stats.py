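"""Threshold classification on region counts and the study statistics.

A subject whose parietal-ROI watershed region count falls at or below the
critical cutoff is called AD-like (reduced number of perfusion domains);
counts above the cutoff are called control-like.  AD is the positive
class throughout.  The module also provides confusion metrics with exact
(Clopper-Pearson) confidence intervals and the pooled two-sample Student
t-test used to compare group mean counts.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportion_confint

AD, CONTROL = "AD", "control"

_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson", "normal": "normal"}


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    group: str
    region_count: int
    predicted: str | None = None

    def __post_init__(self):
        if self.group not in (AD, CONTROL):
            raise ValueError(f"group must be AD or control, got {self.group!r}")
        if self.region_count < 0:
            raise ValueError("region_count must be >= 0")


@dataclasses.dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    sensitivity_ci: tuple[float, float]  # percent bounds
    specificity_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    mean_cis: tuple[tuple[float, float], tuple[float, float]]
    sd_cis: tuple[tuple[float, float], tuple[float, float]]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify_subject(region_count, cutoff: float) -> str:
    """AD when the count is below (or exactly at) the cutoff, else control."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    if region_count < 0:
        raise ValueError("region_count must be >= 0")
    return AD if region_count <= cutoff else CONTROL


def classify_records(records: Sequence[SubjectRecord], cutoff: float) -> list[SubjectRecord]:
    return [
        dataclasses.replace(r, predicted=classify_subject(r.region_count, cutoff))
        for r in records
    ]


def confusion_from_counts(
    tp: int, fp: int, tn: int, fn: int, ci_method: str = "clopper-pearson"
) -> ConfusionMetrics:
    """Sensitivity/specificity (percent) with 95% CIs from a confusion table."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("each group must contain at least one subject")
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    method = _CI_METHODS[ci_method]
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    s_lo, s_hi = proportion_confint(tp, tp + fn, alpha=0.05, method=method)
    p_lo, p_hi = proportion_confint(tn, tn + fp, alpha=0.05, method=method)
    return ConfusionMetrics(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        sensitivity=sens, specificity=spec,
        sensitivity_ci=(100.0 * s_lo, 100.0 * s_hi),
        specificity_ci=(100.0 * p_lo, 100.0 * p_hi),
    )


def confusion_metrics(
    records: Sequence[SubjectRecord], ci_method: str = "clopper-pearson"
) -> ConfusionMetrics:
    """Confusion metrics over classified subject records (AD = positive)."""
    if any(r.predicted is None for r in records):
        raise ValueError("all records must be classified first")
    tp = sum(1 for r in records if r.group == AD and r.predicted == AD)
    fn = sum(1 for r in records if r.group == AD and r.predicted == CONTROL)
    tn = sum(1 for r in records if r.group == CONTROL and r.predicted == CONTROL)
    fp = sum(1 for r in records if r.group == CONTROL and r.predicted == AD)
    return confusion_from_counts(tp, fp, tn, fn, ci_method=ci_method)


def _mean_sd_cis(x: np.ndarray, alpha: float = 0.05):
    n = x.size
    m = float(x.mean())
    s = float(x.std(ddof=1))
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
    mean_ci = (m - t_crit * s / math.sqrt(n), m + t_crit * s / math.sqrt(n))
    chi_hi = stats.chi2.ppf(1 - alpha / 2, n - 1)
    chi_lo = stats.chi2.ppf(alpha / 2, n - 1)
    sd_ci = (
        math.sqrt((n - 1) * s**2 / chi_hi),
        math.sqrt((n - 1) * s**2 / chi_lo),
    )
    return m, s, mean_ci, sd_ci


def two_sample_ttest(counts_a, counts_b, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample Student t-test on group region counts.

    Pooled-variance by default (``equal_var=False`` gives Welch); the t
    statistic is signed as mean(a) - mean(b).  Group means and standard
    deviations are returned with 95% CIs (t-based for the mean,
    chi-square-based for the SD).
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    m_a, s_a, ci_a, sdci_a = _mean_sd_cis(a)
    m_b, s_b, ci_b, sdci_b = _mean_sd_cis(b)
    df = a.size + b.size - 2
    if s_a == 0 and s_b == 0:
        if m_a == m_b:
            t_stat, p = 0.0, 1.0
        else:
            raise OverflowError(
                "t statistic infinite: zero pooled variance with unequal means"
            )
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if not equal_var:
            df = float(res.df)
    return TTestResult(
        t_statistic=t_stat,
        degrees_of_freedom=int(df),
        p_value=p,
        group_means=(m_a, m_b),
        group_sds=(s_a, s_b),
        mean_cis=(ci_a, ci_b),
        sd_cis=(sdci_a, sdci_b),
    )


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled t and two-sided p from group summary statistics."""
    t_stat, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t_stat), float(p)


class RegionCountClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on the watershed region count.

    With ``cutoff=None`` fitting derives the cutoff as the midpoint between
    the two training-group mean counts; a fixed cutoff skips estimation.
    Prediction labels a subject AD when its count is at or below
    ``cutoff_`` and control otherwise.
    """

    def __init__(self, cutoff: float | None = None):
        self.cutoff = cutoff

    def fit(self, X, y):
        counts = np.asarray(X, dtype=np.float64).reshape(-1)
        y = np.asarray(y, dtype=object)
        if counts.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        labels = set(y)
        if not labels <= {AD, CONTROL}:
            raise ValueError(f"labels must be drawn from {{{AD!r}, {CONTROL!r}}}")
        self.classes_ = np.array([AD, CONTROL], dtype=object)
        if self.cutoff is not None:
            self.cutoff_ = float(self.cutoff)
        else:
            if labels != {AD, CONTROL}:
                raise ValueError("deriving a cutoff requires both classes in y")
            m_ad = counts[y == AD].mean()
            m_ctrl = counts[y == CONTROL].mean()
            self.cutoff_ = float((m_ad + m_ctrl) / 2.0)
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        counts = np.asarray(X, dtype=np.float64).reshape(-1)
        return np.where(counts <= self.cutoff_, AD, CONTROL).astype(object)
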