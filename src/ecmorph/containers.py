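"""Shared in-memory containers for calibrated AFM and force-spectroscopy data.

Conventions
-----------
* Height maps are stored in nanometres, row index = slow scan axis,
  column index = fast scan axis; lateral calibration in micrometres per pixel.
* Force curves are stored as ``(n, 2)`` arrays of (position [nm], force [pN]);
  larger positions are further from the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["HeightMap", "ForceCurve"]


@dataclass
class HeightMap:
    """A calibrated 2-D AFM topography image.

    Parameters
    ----------
    heights : ndarray
        2-D array of heights in nm. Row index is the slow scan axis.
    pixel_size_um : float
        Lateral pixel pitch in µm/pixel (square pixels).
    meta : dict
        Free-form provenance metadata, carried through processing steps.
    """

    heights: np.ndarray
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def field_area_um2(self) -> float:
        """Scanned field area in µm²."""
        r, c = self.heights.shape
        return r * c * self.pixel_size_um**2

    def with_heights(self, heights: np.ndarray) -> "HeightMap":
        """Copy of this map with new height data, same calibration."""
        return HeightMap(heights, self.pixel_size_um, dict(self.meta))


MIN_SEGMENT_SAMPLES = 50


@dataclass
class ForceCurve:
    """A force-distance curve (approach + retraction) with probe metadata.

    Each segment is an ``(n, 2)`` array of (position [nm], force [pN]) with
    strictly monotone positions. ``meta`` typically holds spring_constant_N_m,
    speed_um_s, contact_time_s, setpoint_nN, and a cell identifier.
    """

    approach: np.ndarray
    retract: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("approach", "retract"):
            seg = np.asarray(getattr(self, name), dtype=float)
            if seg.ndim != 2 or seg.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            if seg.shape[0] < MIN_SEGMENT_SAMPLES:
                raise ValueError(
                    f"{name} has {seg.shape[0]} samples; "
                    f"at least {MIN_SEGMENT_SAMPLES} required"
                )
            if not np.all(np.isfinite(seg)):
                raise ValueError(f"{name} contains non-finite values")
            d = np.diff(seg[:, 0])
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} positions must be strictly monotone")
            setattr(self, name, seg)

    def segment(self, which: str) -> np.ndarray:
        if which not in ("approach", "retract"):
            raise ValueError("segment must be 'approach' or 'retract'")
        return getattr(self, which)
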