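"""Screen geometry, pixel/degree conversion, and gaze-contingent mask tests.

The display is described by its pixel resolution and the angular radii it
subtends at the viewer: the study display was 1024 x 768 px spanning a
horizontal half-angle of 14.7 deg and a vertical half-angle of 11.2 deg at
71.5 cm. Conversion to degrees is per-axis linear (small-angle scaling)
rather than exact tangent geometry; at 14.7 deg the tangent discrepancy is
below 2% and the linear map has the advantage of being exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "ScreenGeometry",
    "MaskSpec",
    "px_to_deg",
    "deg_to_px",
    "angular_distance",
    "visible",
]


@dataclass
class ScreenGeometry:
    """Display resolution, angular extent, viewing distance and sample rate."""

    width_px: int = 1024
    height_px: int = 768
    half_width_deg: float = 14.7
    half_height_deg: float = 11.2
    viewing_distance_cm: float = 71.5
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "half_width_deg",
            "half_height_deg",
            "viewing_distance_cm",
            "sample_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @property
    def sample_spacing_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


@dataclass
class MaskSpec:
    """Gaze-contingent mask: a window (only the centre visible), a scotoma
    (centre occluded), or no mask. ``radius_deg`` is eccentricity from gaze."""

    mode: str = "none"  # {"window", "scotoma", "none"}
    radius_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("window", "scotoma", "none"):
            raise ValueError(f"unknown mask mode {self.mode!r}")
        if self.mode != "none" and self.radius_deg <= 0:
            raise ValueError("MaskSpec.radius_deg must be > 0 when a mask is active")


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Map screen pixel coordinates to angular offsets from screen centre.

    Linear per-axis scaling: ``x_deg = (x_px - W/2) * half_width_deg / (W/2)``
    and analogously for y. Off-screen coordinates map linearly beyond the
    screen radii. Accepts scalars or arrays.
    """
    sx = geometry.half_width_deg / (geometry.width_px / 2.0)
    sy = geometry.half_height_deg / (geometry.height_px / 2.0)
    x_deg = (np.asarray(x_px, dtype=float) - geometry.width_px / 2.0) * sx
    y_deg = (np.asarray(y_px, dtype=float) - geometry.height_px / 2.0) * sy
    if np.ndim(x_px) == 0 and np.ndim(y_px) == 0:
        return float(x_deg), float(y_deg)
    return x_deg, y_deg


def deg_to_px(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_deg`."""
    sx = geometry.half_width_deg / (geometry.width_px / 2.0)
    sy = geometry.half_height_deg / (geometry.height_px / 2.0)
    x_px = np.asarray(x_deg, dtype=float) / sx + geometry.width_px / 2.0
    y_px = np.asarray(y_deg, dtype=float) / sy + geometry.height_px / 2.0
    if np.ndim(x_deg) == 0 and np.ndim(y_deg) == 0:
        return float(x_px), float(y_px)
    return x_px, y_px


def angular_distance(p1_deg: Tuple[float, float], p2_deg: Tuple[float, float]) -> float:
    """Euclidean distance between two angular offsets, in degrees.

    The degree plane is treated as flat (small-angle convention), which is
    the standard choice for desktop eye tracking at these eccentricities.
    """
    return math.hypot(p2_deg[0] - p1_deg[0], p2_deg[1] - p1_deg[1])


def visible(mask: MaskSpec, gaze_deg: Tuple[float, float], point_deg: Tuple[float, float]) -> bool:
    """Whether ``point_deg`` is visible given gaze position and mask.

    ``window``: visible iff within ``radius_deg`` of gaze (boundary visible).
    ``scotoma``: visible iff strictly beyond ``radius_deg``.
    ``none``: always visible.
    """
    if mask.mode == "none":
        return True
    d = angular_distance(gaze_deg, point_deg)
    if mask.mode == "window":
        return d <= mask.radius_deg
    return d > mask.radius_deg
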