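"""Method-agreement statistics for paired perfusion measurements.

When two software implementations quantify the same recordings, the
question is not whether their outputs correlate but whether they *agree* —
whether one could replace the other.  The machinery implemented here:

* simple OLS regression of one method on the other (the scatter-plot fit);
* Bland–Altman analysis in absolute and relative (percent) modes: the mean
  difference d, the SD of the differences s (n−1 denominator), the limits
  of agreement d ± 1.96 s, and a one-sample t-test of the differences
  against zero (the bias test);
* proportional-bias regression of the differences on the pairwise means;
* a Shapiro–Wilk normality gate for the differences;
* a Mann–Whitney U comparison of a parameter between two outcome groups,
  reported as median (IQR).

Shapiro–Wilk, the t-test and Mann–Whitney are delegated to scipy; OLS
inference to statsmodels.  This module owns the Bland–Altman contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegeneratePairError,
    DegenerateRegressorError,
    InsufficientDataError,
    InvalidInputError,
    ZeroVarianceError,
)

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "RegressionResult",
    "GroupComparison",
    "bland_altman",
    "proportional_bias",
    "method_regression",
    "normality_check",
    "compare_groups",
]

#: Limits-of-agreement multiplier (normal-quantile convention, not t).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-case values of one parameter measured by two methods."""

    case_ids: tuple[str, ...]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(c) for c in self.case_ids)
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "case_ids", ids)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if not (len(ids) == a.size == b.size):
            raise InvalidInputError("case_ids, values_a, values_b must have equal length")
        if len(ids) < 2:
            raise InsufficientDataError("need at least 2 paired cases")
        if len(set(ids)) != len(ids):
            raise InvalidInputError("case_ids must be unique")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidInputError("paired values must be finite")

    @property
    def n(self) -> int:
        return len(self.case_ids)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman summary; units follow the input (or % in relative mode).

    ``p_value_bias`` is ``None`` (flagged undefined) when the differences
    have zero spread, where the one-sample t statistic is undefined.
    """

    mode: str
    mean_difference_d: float
    sd_of_differences_s: float
    loa_lower: float
    loa_upper: float
    t_statistic: Optional[float]
    p_value_bias: Optional[float]
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: slope, intercept, R², F statistic and its p-value."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Mann–Whitney U comparison of one parameter between two groups."""

    u_statistic: float
    p_value: float
    median_group1: float
    iqr_group1: tuple[float, float]
    median_group2: float
    iqr_group2: tuple[float, float]
    n_group1: int
    n_group2: int


def _differences(pairs: PairedMeasurements, mode: str) -> np.ndarray:
    if mode not in ("absolute", "relative_percent"):
        raise InvalidInputError(f"unknown Bland-Altman mode {mode!r}")
    diff = pairs.values_a - pairs.values_b
    if mode == "absolute":
        return diff
    means = (pairs.values_a + pairs.values_b) / 2.0
    zero = means == 0.0
    if np.any(zero):
        offenders = [cid for cid, z in zip(pairs.case_ids, zero) if z]
        raise DegeneratePairError(
            f"pair mean is zero for cases {offenders}; relative difference undefined",
            case_ids=offenders,
        )
    return 100.0 * diff / means


def pair_means(pairs: PairedMeasurements) -> np.ndarray:
    """Per-case mean of the two methods, (A + B)/2."""
    return (pairs.values_a + pairs.values_b) / 2.0


def bland_altman(pairs: PairedMeasurements, mode: str = "absolute") -> BlandAltmanResult:
    """Bland–Altman agreement analysis of method A against method B.

    Differences are ``A - B`` in absolute mode or ``100 (A - B) / mean`` in
    relative mode; d is their sample mean, s their sample SD (n−1), the
    limits of agreement are ``d ± 1.96 s``, and the bias test is a
    one-sample t-test of the differences against zero.
    """
    diff = _differences(pairs, mode)
    d = float(diff.mean())
    s = float(diff.std(ddof=1))
    if s == 0.0:
        t_stat: Optional[float] = None
        p_val: Optional[float] = None
    else:
        res = stats.ttest_1samp(diff, 0.0)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return BlandAltmanResult(
        mode=mode,
        mean_difference_d=d,
        sd_of_differences_s=s,
        loa_lower=d - LOA_MULTIPLIER * s,
        loa_upper=d + LOA_MULTIPLIER * s,
        t_statistic=t_stat,
        p_value_bias=p_val,
        n=pairs.n,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 3:
        raise InsufficientDataError("OLS inference needs at least 3 cases")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressorError("regressor has zero variance")
    if np.ptp(y) == 0.0:
        # constant response: flat fit, nothing explained, no evidence of slope
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            f_statistic=0.0, p_value=1.0, n=int(x.size),
        )
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(x.size),
    )


def proportional_bias(pairs: PairedMeasurements, mode: str = "absolute") -> RegressionResult:
    """OLS of the (absolute or relative) differences on the pairwise means.

    A nonzero slope indicates proportional bias: inter-method differences
    that grow with the magnitude of the measurement.
    """
    diff = _differences(pairs, mode)
    return _ols(pair_means(pairs), diff)


def method_regression(pairs: PairedMeasurements) -> RegressionResult:
    """OLS of method-A values on method-B values (the scatter-plot fit)."""
    return _ols(pairs.values_b, pairs.values_a)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value; a reported gate, not an abort."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise InvalidInputError(f"Shapiro-Wilk needs 3..5000 samples, got {v.size}")
    if np.ptp(v) == 0.0:
        raise ZeroVarianceError("constant input: normality test undefined")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def _median_iqr(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return float(q50), (float(q25), float(q75))


def compare_groups(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann–Whitney U test between two outcome groups.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation otherwise (scipy's ``method='auto'``); each group
    is summarized as median (IQR).
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if g1.size + g2.size < 3:
        raise InsufficientDataError("combined sample too small for inference")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="auto")
    m1, iqr1 = _median_iqr(g1)
    m2, iqr2 = _median_iqr(g2)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_group1=m1,
        iqr_group1=iqr1,
        median_group2=m2,
        iqr_group2=iqr2,
        n_group1=int(g1.size),
        n_group2=int(g2.size),
    )
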