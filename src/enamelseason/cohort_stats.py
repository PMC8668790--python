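"""Comparative statistics: regressions, spacing trends, and cohort tests.

Covers three jobs: ordinary least-squares fits (e.g. interpolated vs.
measured water agreement, carbonate vs. phosphate calibration), the
carbonate-phosphate spacing trend used as a disequilibrium diagnostic,
and Welch's t comparisons between modern and historical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .conversions import co3_po4_spacing
from .core import IsotopeSeries
from .errors import DegenerateDesignError, InsufficientDataError
from .seasonality_metrics import profile_amplitude

__all__ = [
    "RegressionFit",
    "CohortSummary",
    "fit_linear",
    "spacing_trend",
    "welch_t",
    "cohort_offsets",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n: int
    p_slope: float


@dataclass
class CohortSummary:
    """Per-cohort amplitude/level statistics plus the between-cohort test.

    ``mean_offset`` is this cohort's pooled mean minus the other
    cohort's; the t statistic and p value are shared between the pair.
    """

    cohort: str
    amplitudes: np.ndarray
    pooled_values: np.ndarray
    pooled_mean: float
    t_statistic: float
    p_value: float
    df: float
    mean_offset: float
    bone_t: float | None = None
    bone_p: float | None = None
    test_note: str = "Welch unequal-variance two-sided t on pooled replicate means"


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with slope inference.

    R-squared is the squared Pearson correlation; a constant response is
    handled as a zero slope with R-squared defined as 0 (warned), while
    a constant predictor is a degenerate design and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InsufficientDataError("fit_linear needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor is constant; slope undefined")
    if np.ptp(y) == 0:
        warnings.warn("constant response: returning slope 0 with R^2 = 0", stacklevel=2)
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), slope_se=0.0, r_squared=0.0, n=n, p_slope=1.0
        )
    res = scipy.stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=n,
        p_slope=float(res.pvalue),
    )


def spacing_trend(dpo4, dco3) -> RegressionFit:
    """Regression of the carbonate-phosphate spacing on the phosphate value.

    A negative slope means the spacing narrows toward summer (higher
    phosphate) values — the temperature-dependence signature.
    """
    dpo4 = np.asarray(dpo4, dtype=float)
    dco3 = np.asarray(dco3, dtype=float)
    spacing = co3_po4_spacing(dco3, dpo4)
    return fit_linear(dpo4, spacing)


def welch_t(a, b):
    """Welch unequal-variance two-sided t test.

    Returns ``(t, p, df)`` with Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("welch_t needs n >= 2 in each group")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def _pooled(series_list: list[IsotopeSeries], per_specimen: bool) -> np.ndarray:
    if per_specimen:
        return np.array([s.replicate_means().mean() for s in series_list])
    return np.concatenate([s.replicate_means() for s in series_list])


def cohort_offsets(
    modern: list[IsotopeSeries],
    historical: list[IsotopeSeries],
    bone_modern=None,
    bone_historical=None,
    per_specimen: bool = False,
):
    """Compare two cohorts of serial profiles.

    Pools replicate means across each cohort (or collapses to one mean
    per specimen when ``per_specimen``), reports per-specimen
    amplitudes, the between-cohort mean offset, and Welch's t on the
    enamel values (and on bone values when supplied).  Returns a
    ``(modern_summary, historical_summary)`` pair.
    """
    if not modern or not historical:
        raise InsufficientDataError("each cohort needs >= 1 specimen")
    pooled_m = _pooled(modern, per_specimen)
    pooled_h = _pooled(historical, per_specimen)
    t, p, df = welch_t(pooled_m, pooled_h)
    bone_t = bone_p = None
    if bone_modern is not None and bone_historical is not None:
        bone_t, bone_p, _ = welch_t(
            np.asarray(bone_modern, dtype=float), np.asarray(bone_historical, dtype=float)
        )
    amp_m = np.array([profile_amplitude(s.replicate_means()) for s in modern])
    amp_h = np.array([profile_amplitude(s.replicate_means()) for s in historical])
    mean_m = float(pooled_m.mean())
    mean_h = float(pooled_h.mean())
    note = "Welch unequal-variance two-sided t on " + (
        "per-specimen means" if per_specimen else "pooled replicate means"
    )
    summary_m = CohortSummary(
        cohort=modern[0].cohort,
        amplitudes=amp_m,
        pooled_values=pooled_m,
        pooled_mean=mean_m,
        t_statistic=t,
        p_value=p,
        df=df,
        mean_offset=mean_m - mean_h,
        bone_t=bone_t,
        bone_p=bone_p,
        test_note=note,
    )
    summary_h = CohortSummary(
        cohort=historical[0].cohort,
        amplitudes=amp_h,
        pooled_values=pooled_h,
        pooled_mean=mean_h,
        t_statistic=-t,
        p_value=p,
        df=df,
        mean_offset=mean_h - mean_m,
        bone_t=None if bone_t is None else -bone_t,
        bone_p=bone_p,
        test_note=note,
    )
    return summary_m, summary_h
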