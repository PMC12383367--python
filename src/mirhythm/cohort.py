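"""Patient-cohort statistics: group comparison, median stratification,
linear regression, and Kaplan-Meier survival with the log-rank test.

The comparison between tumor and adjacent tissue uses the unpaired
two-sample t-test by default (a paired option exists; note the samples are
in fact paired per patient, so the unpaired default is the conservative
convention adopted here).  Survival curves use the product-limit estimator
with time origin at surgery, and groups are compared by the standard
two-group log-rank test (1 df).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from scipy import stats

__all__ = [
    "compare_groups",
    "stratify_by_median",
    "fit_line",
    "km_curve",
    "km_logrank",
    "MedianSplit",
]


def compare_groups(a, b, equal_var: bool = True, paired: bool = False) -> dict:
    """Two-sided t-test between two groups of values.

    Classical pooled-variance (equal-variance) formula by default; set
    ``equal_var=False`` for Welch's correction or ``paired=True`` for the
    paired test.  Returns t, p, per-group means and standard errors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    # zero-variance groups are resolved explicitly below; silence scipy's
    # catastrophic-cancellation warning for those degenerate inputs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if a.size != b.size:
                raise ValueError("paired test needs equal group sizes")
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # zero variance in both groups
        t = 0.0
        p = 1.0 if a.mean() == b.mean() else 0.0
    return {
        "t": t,
        "p": p,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(stats.sem(a)),
        "sem_b": float(stats.sem(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


@dataclass(frozen=True)
class MedianSplit:
    low: np.ndarray
    high: np.ndarray
    low_mask: np.ndarray
    median: float
    degenerate: bool


def stratify_by_median(values) -> MedianSplit:
    """Partition values at the median: low = value <= median, high = value > median.

    The median is the standard midpoint of the sorted values, so with odd n
    the middle value itself lands in the low group.  All-identical input
    yields an empty high group, flagged degenerate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to stratify")
    med = float(np.median(v))
    low_mask = v <= med
    return MedianSplit(
        low=v[low_mask],
        high=v[~low_mask],
        low_mask=low_mask,
        median=med,
        degenerate=bool(low_mask.all()),
    )


def fit_line(x, y) -> dict:
    """OLS line y = slope*x + intercept with Pearson R and two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": int(x.size),
    }


def _as_event_flags(events) -> np.ndarray:
    ev = np.asarray(events)
    if ev.dtype.kind in "OUS":
        return (ev == "death").astype(int)
    return ev.astype(int)


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with 95% CI.

    ``events`` may be 0/1 flags or the labels ``death``/``censored``.
    Returns a table of (time, at_risk, survival, ci_lower, ci_upper).
    """
    t = np.asarray(times, dtype=float)
    ev = _as_event_flags(events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=ev)
    surv = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    ev_table = kmf.event_table
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(float),
            "at_risk": ev_table["at_risk"].reindex(surv.index).to_numpy(float),
            "survival": surv.iloc[:, 0].to_numpy(float),
            "ci_lower": ci.iloc[:, 0].to_numpy(float),
            "ci_upper": ci.iloc[:, 1].to_numpy(float),
        }
    )
    return out


def km_logrank(times_a, events_a, times_b, events_b) -> dict:
    """Two-group Kaplan-Meier comparison with the log-rank test.

    Returns both groups' survival tables plus the 1-df chi-square statistic
    and p-value.  With no events in either group the test is vacuous:
    chi2 = 0, p = 1.
    """
    ev_a = _as_event_flags(events_a)
    ev_b = _as_event_flags(events_b)
    curve_a = km_curve(times_a, ev_a)
    curve_b = km_curve(times_b, ev_b)
    if ev_a.sum() == 0 and ev_b.sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        res = logrank_test(times_a, times_b, event_observed_A=ev_a, event_observed_B=ev_b)
        chi2, p = float(res.test_statistic), float(res.p_value)
    return {"curve_a": curve_a, "curve_b": curve_b, "chi2": chi2, "p": p}
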