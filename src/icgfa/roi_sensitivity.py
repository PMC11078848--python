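"""Sensitivity of the normalized maximum slope to manual ROI placement.

Clinically, the region of interest is drawn by hand, so two users analysing
the same recording place slightly different boxes.  This module quantifies
that: around an original ROI it builds four "inner" ROIs (small
displacements mimicking inter-user variation) and four "outer" ROIs (larger
displacements along the conduit axis), extracts and quantifies each with a
given algorithm profile, and reports per-ROI percent deviation from the
original value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError
from .parameters import AlgorithmProfile, quantify
from .trace import ROISpec, displace_roi, extract_trace

__all__ = [
    "ROISensitivityReport",
    "build_roi_grid",
    "percent_deviation",
    "sensitivity_analysis",
]


@dataclass(frozen=True)
class ROIEntry:
    label: str
    roi: ROISpec
    value: float
    percent_deviation: float


@dataclass(frozen=True)
class ROISensitivityReport:
    """Per-ROI normalized maximum slopes and deviations from the original.

    ``inner_range`` and ``outer_range`` are (min %, max %) over the four
    inner and four outer ROIs respectively.
    """

    original_value: float
    per_roi: tuple[ROIEntry, ...]
    inner_range: tuple[float, float]
    outer_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "original_value_per_s": self.original_value,
            "per_roi": [
                {
                    "label": e.label,
                    "x": e.roi.x,
                    "y": e.roi.y,
                    "width": e.roi.width,
                    "height": e.roi.height,
                    "normalized_max_slope_per_s": e.value,
                    "percent_deviation": e.percent_deviation,
                }
                for e in self.per_roi
            ],
            "inner_range_percent": list(self.inner_range),
            "outer_range_percent": list(self.outer_range),
        }


def build_roi_grid(
    original: ROISpec,
    inner_offset: int,
    outer_offset: int,
    conduit_axis: str = "x",
) -> list[ROISpec]:
    """Eight displaced copies of the original ROI, labels ROI2..ROI9.

    Fixed order: the four inner ROIs first — displaced by −/+``inner_offset``
    along x (ROI2, ROI3) then along y (ROI4, ROI5) — followed by the four
    outer ROIs along the conduit axis at −2, −1, +1, +2 × ``outer_offset``
    (ROI6..ROI9).  The conduit axis defaults to the image x-axis.
    """
    if conduit_axis not in ("x", "y"):
        raise ValueError(f"conduit_axis must be 'x' or 'y', got {conduit_axis!r}")
    inner = [
        displace_roi(original, -inner_offset, 0),
        displace_roi(original, +inner_offset, 0),
        displace_roi(original, 0, -inner_offset),
        displace_roi(original, 0, +inner_offset),
    ]
    steps = (-2, -1, +1, +2)
    if conduit_axis == "x":
        outer = [displace_roi(original, s * outer_offset, 0) for s in steps]
    else:
        outer = [displace_roi(original, 0, s * outer_offset) for s in steps]
    rois = inner + outer
    return [
        ROISpec(x=r.x, y=r.y, width=r.width, height=r.height, label=f"ROI{i + 2}")
        for i, r in enumerate(rois)
    ]


def percent_deviation(value: float, reference: float) -> float:
    """Percent deviation of *value* from *reference*: 100 (value − ref)/ref."""
    if reference == 0:
        raise DegenerateReferenceError("reference value is zero")
    return 100.0 * (value - reference) / reference


def sensitivity_analysis(
    frames: np.ndarray,
    original: ROISpec,
    profile: AlgorithmProfile,
    frame_rate: float,
    inner_offset: int | None = None,
    outer_offset: int | None = None,
    conduit_axis: str = "x",
    channel_policy: str = "grayscale",
) -> ROISensitivityReport:
    """Quantify the original and eight displaced ROIs on one recording.

    Default offsets echo a hand-displacement layout: inner = half the ROI
    width, outer = twice the ROI width.  Deterministic for deterministic
    inputs.
    """
    if inner_offset is None:
        inner_offset = max(original.width // 2, 1)
    if outer_offset is None:
        outer_offset = 2 * original.width

    def value_of(roi: ROISpec) -> float:
        trace = extract_trace(frames, roi, frame_rate, channel_policy)
        return quantify(trace, profile).normalized_max_slope

    original_value = value_of(original)
    entries = []
    for roi in build_roi_grid(original, inner_offset, outer_offset, conduit_axis):
        val = value_of(roi)
        entries.append(
            ROIEntry(
                label=roi.label,
                roi=roi,
                value=val,
                percent_deviation=percent_deviation(val, original_value),
            )
        )
    inner_devs = [e.percent_deviation for e in entries[:4]]
    outer_devs = [e.percent_deviation for e in entries[4:]]
    return ROISensitivityReport(
        original_value=original_value,
        per_roi=tuple(entries),
        inner_range=(min(inner_devs), max(inner_devs)),
        outer_range=(min(outer_devs), max(outer_devs)),
    )
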