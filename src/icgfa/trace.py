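"""Fluorescence time curves and ROI-based extraction from frame stacks.

The fluorescence time curve (FTC) is the mean pixel intensity within a
rectangular region of interest (ROI), one value per video frame, plotted
against time.  Both quantification algorithms implemented in this package
operate on this ROI-mean trace; they differ only downstream, in smoothing
and slope extraction.

Pixel coordinate convention: 0-based, origin at the top-left corner,
half-open intervals — an ROI covers columns ``[x, x + width)`` and rows
``[y, y + height)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import BoundsError, InvalidInputError, InvalidParameterError

__all__ = [
    "FluorescenceTrace",
    "ROISpec",
    "extract_trace",
    "displace_roi",
    "read_trace_csv",
    "write_trace_csv",
    "load_frame_stack",
]

#: ITU-R BT.601 luma weights for RGB → gray conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_CHANNEL_POLICIES = ("grayscale", "green_channel", "luma")


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular region of interest.

    Parameters
    ----------
    x, y : int
        Left edge (column) and top edge (row) in pixels, 0-based.
    width, height : int
        Extent in pixels; the ROI is the half-open box
        ``[x, x+width) x [y, y+height)``.
    label : str
        Free-text identifier carried through reports.
    """

    x: int
    y: int
    width: int
    height: int
    label: str = "ROI"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError(
                f"ROI width and height must be positive, got {self.width}x{self.height}"
            )

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) center of the box in pixel coordinates."""
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    def slices(self) -> tuple[slice, slice]:
        """(row_slice, col_slice) for indexing a (H, W) frame."""
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


@dataclass(frozen=True)
class FluorescenceTrace:
    """Uniformly sampled fluorescence-vs-time series in arbitrary units (AU).

    ``times`` must be strictly increasing with uniform spacing
    ``dt = 1 / frame_rate``; ``smoothed_by`` records the smoothing
    descriptor for conditioned traces and is ``None`` for raw traces.
    """

    times: np.ndarray
    intensities: np.ndarray
    frame_rate: float
    smoothed_by: Optional[object] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise InvalidInputError("times and intensities must be 1-D arrays")
        if times.size != intensities.size:
            raise InvalidInputError(
                f"length mismatch: {times.size} times vs {intensities.size} intensities"
            )
        if times.size < 2:
            raise InvalidInputError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(intensities)) or not np.all(np.isfinite(times)):
            raise InvalidInputError("trace contains non-finite values")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise InvalidInputError("times must be strictly increasing")
        mean_dt = dt.mean()
        if np.any(np.abs(dt - mean_dt) > 1e-9 * max(mean_dt, 1.0)):
            raise InvalidInputError("times must be uniformly spaced")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Time span covered by the trace, in seconds."""
        return float(self.times[-1] - self.times[0])

    def with_intensities(self, intensities: np.ndarray, smoothed_by=None) -> "FluorescenceTrace":
        """Same time base, new intensity values (used by the smoothers)."""
        return FluorescenceTrace(
            times=self.times.copy(),
            intensities=np.asarray(intensities, dtype=float),
            frame_rate=self.frame_rate,
            smoothed_by=smoothed_by,
        )


def displace_roi(roi: ROISpec, dx: int, dy: int) -> ROISpec:
    """Return a copy of *roi* shifted by (dx, dy) pixels.

    Bounds are not checked here; they are validated when the ROI is applied
    to a frame stack.  The label records the displacement.
    """
    if dx == 0 and dy == 0:
        label = roi.label
    else:
        label = f"{roi.label}+({dx:+d},{dy:+d})"
    return replace(roi, x=roi.x + dx, y=roi.y + dy, label=label)


def _select_channel(frames: np.ndarray, channel_policy: str) -> np.ndarray:
    """Reduce a (T, H, W) or (T, H, W, C) stack to single-channel (T, H, W)."""
    if channel_policy not in _CHANNEL_POLICIES:
        raise InvalidParameterError(
            f"unknown channel_policy {channel_policy!r}; expected one of {_CHANNEL_POLICIES}"
        )
    if frames.ndim == 3:
        if channel_policy != "grayscale":
            raise InvalidParameterError(
                f"channel_policy {channel_policy!r} requires multi-channel frames, "
                "but the stack is single-channel"
            )
        return frames
    if frames.ndim == 4:
        n_channels = frames.shape[-1]
        if channel_policy == "grayscale":
            raise InvalidParameterError(
                "channel_policy 'grayscale' expects single-channel frames; "
                "use 'green_channel' or 'luma' for multi-channel stacks"
            )
        if n_channels < 3:
            raise InvalidParameterError(
                f"{channel_policy!r} needs at least 3 channels, stack has {n_channels}"
            )
        if channel_policy == "green_channel":
            return frames[..., 1]
        return np.tensordot(frames[..., :3].astype(float), _LUMA_WEIGHTS, axes=([-1], [0]))
    raise InvalidInputError(
        f"frame stack must be (T, H, W) or (T, H, W, C); got shape {frames.shape}"
    )


def extract_trace(
    frames: np.ndarray,
    roi: ROISpec,
    frame_rate: float,
    channel_policy: str = "grayscale",
) -> FluorescenceTrace:
    """Extract the ROI-mean fluorescence time curve from a frame stack.

    The intensity at frame *i* is the arithmetic mean of the selected-channel
    pixel values inside the ROI of frame *i*; the time axis is ``i / frame_rate``.

    Parameters
    ----------
    frames : ndarray
        Stack of shape (T, H, W) for single-channel or (T, H, W, C) for
        multi-channel video.
    roi : ROISpec
        Region over which to average; must lie fully inside the frame.
    frame_rate : float
        Acquisition rate in frames per second.
    channel_policy : {'grayscale', 'green_channel', 'luma'}
        How to collapse multi-channel pixels to a scalar intensity.
    """
    frames = np.asarray(frames)
    if frames.size == 0 or frames.shape[0] == 0:
        raise InvalidInputError("empty frame stack")
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    mono = _select_channel(frames, channel_policy)
    n_frames, height, width = mono.shape
    if roi.x < 0 or roi.y < 0 or roi.x + roi.width > width or roi.y + roi.height > height:
        raise BoundsError(
            f"ROI {roi.label!r} [{roi.x}:{roi.x + roi.width}) x [{roi.y}:{roi.y + roi.height}) "
            f"exceeds frame bounds {width}x{height}"
        )
    rows, cols = roi.slices()
    intensities = mono[:, rows, cols].astype(float).mean(axis=(1, 2))
    times = np.arange(n_frames, dtype=float) / frame_rate
    return FluorescenceTrace(times=times, intensities=intensities, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# File formats

def write_trace_csv(trace: FluorescenceTrace, path: str | os.PathLike) -> None:
    """Write the standard two-column trace CSV (``time_s,intensity_au``)."""
    df = pd.DataFrame({"time_s": trace.times, "intensity_au": trace.intensities})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | os.PathLike, frame_rate: float | None = None) -> FluorescenceTrace:
    """Read a two-column trace CSV.

    If *frame_rate* is omitted it is inferred from the median time step.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "intensity_au"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    if frame_rate is None:
        if times.size < 2:
            raise InvalidInputError(f"{path}: too few rows to infer frame rate")
        frame_rate = 1.0 / float(np.median(np.diff(times)))
    return FluorescenceTrace(
        times=times,
        intensities=df["intensity_au"].to_numpy(dtype=float),
        frame_rate=frame_rate,
    )


def load_frame_stack(path: str | os.PathLike) -> np.ndarray:
    """Load a frame stack from a multi-page TIFF, a directory of numbered
    PNG frames, or a video container readable by imageio.

    Returns an array of shape (T, H, W) or (T, H, W, C).
    """
    path = Path(path)
    if path.is_dir():
        frame_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not frame_files:
            raise InvalidInputError(f"{path}: no PNG/TIFF frames found")
        import imageio.v3 as iio

        return np.stack([iio.imread(p) for p in frame_files])
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
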