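"""Seeded synthetic fluorescence-angiography recordings with known ground truth.

Real intraoperative ICG-FA videos are not publicly deposited, so this module
generates surrogate recordings with the anatomy of a standardized
pre-anastomosis acquisition: a flat baseline at ``F0``, a bolus inflow phase
rising to ``Fmax`` over seconds to tens of seconds, an exponential washout
toward a plateau, additive Gaussian sensor noise, and an optional sinusoidal
intensity oscillation standing in for respiratory motion.

Two rise shapes are supported because both admit closed-form ground truth
for the normalized maximum slope (the quantity every estimator in this
package targets):

* ``linear`` — a ramp of duration ``T``; normalized maximum slope ``1/T``.
* ``logistic`` — a sigmoid with steepness ``k`` (1/s); the derivative peaks
  at ``k (Fmax - F0) / 4``, so the normalized maximum slope is ``k/4``.

The logistic is centered 6/k seconds after onset, so the curve sits within
0.25% of baseline at the nominal onset time and within 0.25% of the peak at
``onset_time + 12/k``, where washout takes over.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Mapping, Union

import numpy as np

from .errors import InvalidParameterError
from .trace import FluorescenceTrace

__all__ = [
    "PerfusionCurveParams",
    "AcquisitionParams",
    "NoiseParams",
    "SyntheticRecording",
    "FrameStackRecording",
    "generate_trace",
    "generate_frame_stack",
    "ground_truth_normalized_max_slope",
    "noiseless_curve",
]

#: Sigmoid offset (in units of 1/k) between nominal onset and logistic center.
#: exp(-6) ≈ 0.0025, so the curve is within 0.25% of its asymptotes at the
#: nominal onset and rise-end times.
_LOGISTIC_TAIL = 6.0


@dataclass(frozen=True)
class PerfusionCurveParams:
    """Analytic inflow/washout model of a single perfusion curve.

    Parameters
    ----------
    baseline_intensity : float
        Pre-bolus fluorescence F0, in AU; must be >= 0.
    peak_intensity : float
        Peak fluorescence Fmax, in AU; must exceed the baseline.
    onset_time : float
        Bolus arrival t0 in seconds.
    rise_shape : {'linear', 'logistic'}
        Kinetic form of the inflow phase.
    rise_duration_or_rate : float
        For 'linear': time from onset to peak, seconds.
        For 'logistic': steepness k, 1/seconds.
    washout_rate : float
        Exponential decay rate toward the plateau after the peak, 1/seconds;
        0 disables washout.
    plateau_fraction : float
        Washout asymptote as a fraction of the peak intensity, in [0, 1].
    """

    baseline_intensity: float
    peak_intensity: float
    onset_time: float
    rise_shape: str = "linear"
    rise_duration_or_rate: float = 20.0
    washout_rate: float = 0.0
    plateau_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.baseline_intensity < 0:
            raise InvalidParameterError("baseline_intensity must be >= 0")
        if self.peak_intensity <= self.baseline_intensity:
            raise InvalidParameterError("peak_intensity must exceed baseline_intensity")
        if self.onset_time < 0:
            raise InvalidParameterError("onset_time must be >= 0")
        if self.rise_shape not in ("linear", "logistic"):
            raise InvalidParameterError(f"unknown rise_shape {self.rise_shape!r}")
        if self.rise_duration_or_rate <= 0:
            raise InvalidParameterError("rise_duration_or_rate must be positive")
        if self.washout_rate < 0:
            raise InvalidParameterError("washout_rate must be >= 0")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise InvalidParameterError("plateau_fraction must be in [0, 1]")

    @property
    def rise_end_time(self) -> float:
        """Time at which the inflow phase hands over to washout, seconds."""
        if self.rise_shape == "linear":
            return self.onset_time + self.rise_duration_or_rate
        return self.onset_time + 2.0 * _LOGISTIC_TAIL / self.rise_duration_or_rate


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera acquisition settings: frame rate, duration, optional saturation."""

    frame_rate: float = 25.0
    duration: float = 200.0
    intensity_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.duration * self.frame_rate < 2:
            raise InvalidParameterError("recording must span at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise model: white Gaussian sensor noise plus a sinusoidal
    intensity oscillation emulating respiratory motion."""

    gaussian_sd: float = 0.0
    motion_amplitude: float = 0.0
    motion_frequency: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise InvalidParameterError("gaussian_sd must be >= 0")
        if self.motion_amplitude < 0:
            raise InvalidParameterError("motion_amplitude must be >= 0")
        if self.motion_frequency < 0:
            raise InvalidParameterError("motion_frequency must be >= 0")


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated trace together with the analytic truth that produced it."""

    trace: FluorescenceTrace
    ground_truth: PerfusionCurveParams
    ground_truth_normalized_max_slope: float
    acquisition: AcquisitionParams
    noise: NoiseParams


@dataclass(frozen=True)
class FrameStackRecording:
    """A generated frame stack plus its per-region ground-truth manifest."""

    frames: np.ndarray
    region_map: np.ndarray
    manifest: dict
    acquisition: AcquisitionParams
    noise: NoiseParams


def ground_truth_normalized_max_slope(curve: PerfusionCurveParams) -> float:
    """Analytic maximum of dF/dt divided by (Fmax - F0), in 1/seconds.

    Linear ramp of duration T → 1/T; logistic of steepness k → k/4.
    """
    if curve.rise_duration_or_rate <= 0:
        raise InvalidParameterError("degenerate rise: duration/rate must be positive")
    if curve.rise_shape == "linear":
        return 1.0 / curve.rise_duration_or_rate
    return curve.rise_duration_or_rate / 4.0


def noiseless_curve(curve: PerfusionCurveParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the analytic perfusion curve (no noise) at the given times."""
    t = np.asarray(times, dtype=float)
    f0 = curve.baseline_intensity
    fmax = curve.peak_intensity
    rng_au = fmax - f0
    t_end = curve.rise_end_time

    out = np.full_like(t, f0)
    if curve.rise_shape == "linear":
        rising = (t >= curve.onset_time) & (t < t_end)
        out[rising] = f0 + rng_au * (t[rising] - curve.onset_time) / curve.rise_duration_or_rate
        peak_value = fmax
    else:
        k = curve.rise_duration_or_rate
        center = curve.onset_time + _LOGISTIC_TAIL / k
        rising = t < t_end
        # the sigmoid's lower tail doubles as the baseline: below 0.25% of
        # the range before the nominal onset, so no splice discontinuity
        out[rising] = f0 + rng_au / (1.0 + np.exp(-k * (t[rising] - center)))
        peak_value = f0 + rng_au / (1.0 + np.exp(-_LOGISTIC_TAIL))

    after = t >= t_end
    if np.any(after):
        if curve.washout_rate == 0:
            out[after] = peak_value
        else:
            plateau = curve.plateau_fraction * fmax
            out[after] = plateau + (peak_value - plateau) * np.exp(
                -curve.washout_rate * (t[after] - t_end)
            )
    return out


def generate_trace(
    curve: PerfusionCurveParams,
    acq: AcquisitionParams,
    noise: NoiseParams,
) -> SyntheticRecording:
    """Generate one seeded synthetic recording.

    The noiseless component equals the baseline before onset, follows the
    configured rise shape to the peak, then decays exponentially toward the
    plateau.  Noise is additive: white Gaussian with SD ``gaussian_sd`` plus
    a sinusoid of amplitude ``motion_amplitude`` at ``motion_frequency``
    with a seeded random phase.  Identical (parameters, seed) reproduce the
    trace bit-for-bit.
    """
    if curve.rise_end_time > acq.duration:
        raise InvalidParameterError(
            f"rise completes at {curve.rise_end_time:.1f}s, after the recording "
            f"ends at {acq.duration:.1f}s"
        )
    times = np.arange(acq.n_frames, dtype=float) / acq.frame_rate
    clean = noiseless_curve(curve, times)

    rng = np.random.default_rng(noise.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    values = clean + rng.normal(0.0, noise.gaussian_sd, size=times.size)
    if noise.motion_amplitude > 0 and noise.motion_frequency > 0:
        values = values + noise.motion_amplitude * np.sin(
            2.0 * np.pi * noise.motion_frequency * times + phase
        )
    if acq.intensity_ceiling is not None:
        values = np.minimum(values, acq.intensity_ceiling)

    trace = FluorescenceTrace(times=times, intensities=values, frame_rate=acq.frame_rate)
    return SyntheticRecording(
        trace=trace,
        ground_truth=curve,
        ground_truth_normalized_max_slope=ground_truth_normalized_max_slope(curve),
        acquisition=acq,
        noise=noise,
    )


CurveField = Union[
    Callable[[int, int], PerfusionCurveParams],
    Mapping[tuple[int, int], PerfusionCurveParams],
]


def generate_frame_stack(
    curve_field: CurveField,
    acq: AcquisitionParams,
    noise: NoiseParams,
    frame_shape: tuple[int, int],
) -> FrameStackRecording:
    """Generate a synthetic grayscale frame stack with a spatial perfusion map.

    ``curve_field`` maps a pixel position ``(row, col)`` to the
    :class:`PerfusionCurveParams` governing that pixel; it may be a callable
    or a mapping and must be defined for every pixel.  Each pixel's series is
    an independent noisy realization of its curve.  The manifest groups
    pixels sharing identical parameters into labeled regions with their
    analytic normalized maximum slope.

    Returns a :class:`FrameStackRecording` whose ``frames`` array has shape
    (T, H, W) in float AU and whose ``region_map`` assigns each pixel its
    region index.
    """
    height, width = frame_shape
    if height <= 0 or width <= 0:
        raise InvalidParameterError("frame_shape must be positive")

    lookup: Callable[[int, int], PerfusionCurveParams]
    if callable(curve_field):
        lookup = curve_field
    else:
        def lookup(row: int, col: int) -> PerfusionCurveParams:
            try:
                return curve_field[(row, col)]
            except KeyError as exc:
                raise InvalidParameterError(
                    f"curve_field undefined for pixel ({row}, {col})"
                ) from exc

    region_of: dict[PerfusionCurveParams, int] = {}
    region_map = np.empty((height, width), dtype=int)
    for row in range(height):
        for col in range(width):
            params = lookup(row, col)
            if not isinstance(params, PerfusionCurveParams):
                raise InvalidParameterError(
                    f"curve_field returned {type(params).__name__} for pixel "
                    f"({row}, {col}); expected PerfusionCurveParams"
                )
            if params not in region_of:
                region_of[params] = len(region_of)
            region_map[row, col] = region_of[params]

    times = np.arange(acq.n_frames, dtype=float) / acq.frame_rate
    frames = np.empty((acq.n_frames, height, width), dtype=float)
    regions = []
    for params, index in region_of.items():
        if params.rise_end_time > acq.duration:
            raise InvalidParameterError(
                f"region {index}: rise completes after the recording ends"
            )
        mask = region_map == index
        frames[:, mask] = noiseless_curve(params, times)[:, None]
        regions.append(
            {
                "label": f"region_{index}",
                "n_pixels": int(mask.sum()),
                "curve": asdict(params),
                "normalized_max_slope_true": ground_truth_normalized_max_slope(params),
            }
        )

    rng = np.random.default_rng(noise.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(height, width))
    if noise.gaussian_sd > 0:
        frames += rng.normal(0.0, noise.gaussian_sd, size=frames.shape)
    if noise.motion_amplitude > 0 and noise.motion_frequency > 0:
        frames += noise.motion_amplitude * np.sin(
            2.0 * np.pi * noise.motion_frequency * times[:, None, None] + phases[None, :, :]
        )
    if acq.intensity_ceiling is not None:
        np.minimum(frames, acq.intensity_ceiling, out=frames)

    manifest = {
        "frame_shape": [height, width],
        "frame_rate": acq.frame_rate,
        "duration": acq.duration,
        "seed": noise.seed,
        "regions": regions,
    }
    return FrameStackRecording(
        frames=frames,
        region_map=region_map,
        manifest=manifest,
        acquisition=acq,
        noise=noise,
    )
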