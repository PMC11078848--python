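"""Fluorescence time-curve parameters and the two maximum-slope estimators.

The quantitative readout of an ICG-FA recording is a small set of curve
parameters: the baseline intensity F0, the peak Fmax and its time tmax, the
onset t0 (first intensity significantly above baseline), the time to peak
ttp = tmax - t0, the mean inflow slope (Fmax - F0)/ttp, the decay times t90
and t80, and — centrally — the *normalized maximum slope*

    max slope        = max over t of (F(t) - F(t - dt)) / dt
    normalized slope = max slope / (Fmax - F0)        [units 1/s]

Normalization by the intensity range makes the parameter insensitive to
camera gain, distance and angle, which scale intensities affinely.

Two estimators of the maximum slope are implemented:

* ``pointwise`` — the single highest adjacent-frame difference quotient over
  the entire recording (the AMS recipe, applied after Butterworth
  filtering);
* ``windowed`` — an ordinary-least-squares slope of intensity versus time
  over a window of ±``half_width`` frames (default 25, i.e. 50 frames ≈ 2 s
  at 25 fps) anchored at the pointwise argmax (the CPH recipe, applied
  after Lanczos smoothing).

Because an OLS slope is a convex combination of pairwise secant slopes, and
every multi-frame secant is an average of adjacent-frame quotients, the
windowed estimate can never exceed the pointwise one on the same trace —
the structural reason one recipe reads systematically lower than the other,
increasingly so for steep curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateRangeError,
    InvalidInputError,
    InvalidIntervalError,
    InvalidParameterError,
    NoOnsetError,
)
from .smoothing import SmoothingDescriptor, apply_smoothing
from .trace import FluorescenceTrace

__all__ = [
    "AlgorithmProfile",
    "FTCParameters",
    "AMS_PROFILE",
    "CPH_PROFILE",
    "detect_t0",
    "detect_peak",
    "max_slope_pointwise",
    "max_slope_windowed",
    "normalize_slope",
    "mean_slope",
    "decay_times",
    "quantify",
]


@dataclass(frozen=True)
class AlgorithmProfile:
    """A named quantification recipe binding a smoother to a slope estimator.

    The two built-in profiles mirror the independently developed softwares
    this package compares:

    * ``AMS`` — Butterworth smoothing + pointwise maximum derivative;
    * ``CPH`` — Lanczos smoothing + windowed OLS regression.

    ``custom`` allows any combination.  The onset-detection rule ("first
    intensity significantly above baseline") is concretized as baseline mean
    + ``t0_sd_multiplier`` × baseline SD, with the baseline statistics taken
    over the first ``t0_baseline_window`` seconds.
    """

    name: str = "custom"
    smoothing: SmoothingDescriptor = field(default_factory=SmoothingDescriptor)
    slope_method: str = "pointwise_max"
    window_half_width: int = 25
    t0_baseline_window: float = 5.0
    t0_sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.name not in ("AMS", "CPH", "custom"):
            raise InvalidParameterError(f"unknown profile name {self.name!r}")
        if self.slope_method not in ("pointwise_max", "windowed_regression"):
            raise InvalidParameterError(f"unknown slope_method {self.slope_method!r}")
        if self.window_half_width < 1:
            raise InvalidParameterError("window_half_width must be >= 1")
        if self.t0_baseline_window <= 0:
            raise InvalidParameterError("t0_baseline_window must be positive")
        if self.name == "AMS" and not (
            self.smoothing.method == "butterworth" and self.slope_method == "pointwise_max"
        ):
            raise InvalidParameterError("AMS profile requires butterworth + pointwise_max")
        if self.name == "CPH" and not (
            self.smoothing.method == "lanczos" and self.slope_method == "windowed_regression"
        ):
            raise InvalidParameterError("CPH profile requires lanczos + windowed_regression")


#: Butterworth smoothing + pointwise maximum derivative.
AMS_PROFILE = AlgorithmProfile(
    name="AMS",
    smoothing=SmoothingDescriptor(method="butterworth"),
    slope_method="pointwise_max",
)

#: Lanczos smoothing + windowed OLS slope (±25 frames around the argmax).
CPH_PROFILE = AlgorithmProfile(
    name="CPH",
    smoothing=SmoothingDescriptor(method="lanczos"),
    slope_method="windowed_regression",
)


@dataclass(frozen=True)
class FTCParameters:
    """The full set of curve-derived quantities for one (recording, profile)."""

    F0: float
    Fmax: float
    t0: float
    t_max: float
    ttp: float
    mean_slope: float
    max_slope: float
    normalized_max_slope: float
    t90: Optional[float]
    t80: Optional[float]
    profile: AlgorithmProfile


def detect_t0(
    trace: FluorescenceTrace,
    baseline_window: float = 5.0,
    sd_multiplier: float = 3.0,
) -> float:
    """Onset time: earliest sample exceeding baseline mean + multiplier × SD.

    Baseline statistics are computed over the first ``baseline_window``
    seconds.  Raises :class:`NoOnsetError` when no sample ever exceeds the
    threshold (e.g. a strictly constant trace).
    """
    if baseline_window <= 0:
        raise InvalidParameterError("baseline_window must be positive")
    if trace.duration <= baseline_window:
        raise InvalidInputError(
            f"trace spans {trace.duration:.2f}s, not longer than the "
            f"{baseline_window:.2f}s baseline window"
        )
    n_base = max(int(round(baseline_window * trace.frame_rate)), 2)
    base = trace.intensities[:n_base]
    threshold = base.mean() + sd_multiplier * base.std(ddof=1)
    above = np.nonzero(trace.intensities > threshold)[0]
    if above.size == 0:
        raise NoOnsetError(
            f"no sample exceeds the onset threshold {threshold:.3f} AU"
        )
    return float(trace.times[above[0]])


def detect_peak(trace: FluorescenceTrace) -> tuple[float, float]:
    """(Fmax, t_max): global intensity maximum and its earliest time."""
    idx = int(np.argmax(trace.intensities))  # argmax returns the first maximum
    return float(trace.intensities[idx]), float(trace.times[idx])


def max_slope_pointwise(trace: FluorescenceTrace) -> tuple[float, float]:
    """Maximum adjacent-frame difference quotient over the whole recording.

    Returns ``(slope, at_time)`` where ``at_time`` is the right endpoint of
    the maximizing interval; the earliest tie wins.
    """
    if len(trace) < 2:
        raise InvalidInputError("need at least 2 samples for a slope")
    quotients = np.diff(trace.intensities) / trace.dt
    idx = int(np.argmax(quotients))
    return float(quotients[idx]), float(trace.times[idx + 1])


def max_slope_windowed(
    trace: FluorescenceTrace, half_width: int = 25
) -> tuple[float, tuple[int, int]]:
    """OLS slope over a frame window centered on the pointwise argmax.

    The window spans ``half_width`` frames on each side of the point of
    maximum pointwise slope, truncated at the recording ends.  Returns
    ``(slope, (first_frame, last_frame))`` with an inclusive frame interval.
    """
    if len(trace) < 2:
        raise InvalidInputError("need at least 2 samples for a slope")
    if half_width < 1:
        raise InvalidParameterError("half_width must be >= 1")
    quotients = np.diff(trace.intensities) / trace.dt
    anchor = int(np.argmax(quotients))  # left endpoint of the steepest interval
    # center the window on the steepest adjacent-frame interval
    lo = max(anchor - half_width + 1, 0)
    hi = min(anchor + 1 + half_width, len(trace) - 1)
    t = trace.times[lo : hi + 1]
    y = trace.intensities[lo : hi + 1]
    tc = t - t.mean()
    slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    return slope, (lo, hi)


def normalize_slope(max_slope: float, Fmax: float, F0: float) -> float:
    """Normalized maximum slope: ``max_slope / (Fmax - F0)``, units 1/s."""
    if Fmax <= F0:
        raise DegenerateRangeError(
            f"Fmax ({Fmax}) must exceed F0 ({F0}) for normalization"
        )
    return max_slope / (Fmax - F0)


def mean_slope(t0: float, t_max: float, Fmax: float, F0: float) -> float:
    """Mean inflow slope ``(Fmax - F0)/(t_max - t0)``, AU/s."""
    if t_max <= t0:
        raise InvalidIntervalError(f"t_max ({t_max}) must exceed t0 ({t0})")
    return (Fmax - F0) / (t_max - t0)


def decay_times(
    trace: FluorescenceTrace,
    t_max: float,
    Fmax: float,
    fractions: Sequence[float] = (0.9, 0.8),
) -> dict[float, Optional[float]]:
    """Earliest post-peak times at which intensity falls to each fraction of Fmax.

    For each fraction f the value is the earliest time after ``t_max`` with
    intensity ≤ f × Fmax, or ``None`` when the curve never drops that far
    within the recording (absence is a value, not an error).
    """
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise InvalidParameterError(f"fractions must lie in (0, 1), got {f}")
    after = trace.times > t_max
    times = trace.times[after]
    values = trace.intensities[after]
    out: dict[float, Optional[float]] = {}
    for f in fractions:
        hit = np.nonzero(values <= f * Fmax)[0]
        out[f] = float(times[hit[0]]) if hit.size else None
    return out


def _baseline_f0(trace: FluorescenceTrace, t0: float) -> float:
    """Baseline intensity: mean of the smoothed trace strictly before onset
    (falls back to the first sample when onset is at the first frame)."""
    before = trace.times < t0
    if not np.any(before):
        return float(trace.intensities[0])
    return float(trace.intensities[before].mean())


def quantify(trace: FluorescenceTrace, profile: AlgorithmProfile) -> FTCParameters:
    """Full quantification of a raw trace under an algorithm profile.

    Applies the profile's smoother, detects onset, peak and decay times on
    the smoothed curve, computes the profile's maximum-slope variant, and
    normalizes by the smoothed curve's intensity range.  AMS and CPH
    profiles differ only in (smoother, slope method), so any cross-profile
    difference is attributable to those two choices.
    """
    if trace.smoothed_by is not None:
        raise InvalidInputError("quantify expects a raw (unsmoothed) trace")
    smooth = apply_smoothing(trace, profile.smoothing)
    t0 = detect_t0(smooth, profile.t0_baseline_window, profile.t0_sd_multiplier)
    Fmax, t_max = detect_peak(smooth)
    F0 = _baseline_f0(smooth, t0)
    if profile.slope_method == "pointwise_max":
        slope, _ = max_slope_pointwise(smooth)
    else:
        slope, _ = max_slope_windowed(smooth, profile.window_half_width)
    nms = normalize_slope(slope, Fmax, F0)
    mslope = mean_slope(t0, t_max, Fmax, F0) if t_max > t0 else math.nan
    decays = decay_times(smooth, t_max, Fmax, (0.9, 0.8))
    return FTCParameters(
        F0=F0,
        Fmax=Fmax,
        t0=t0,
        t_max=t_max,
        ttp=t_max - t0,
        mean_slope=mslope,
        max_slope=slope,
        normalized_max_slope=nms,
        t90=decays[0.9],
        t80=decays[0.8],
        profile=profile,
    )
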