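"""Macrophage-rich region detection from CD68-positive pixel masks.

Immunohistochemistry marks macrophages with CD68; a plaque location is
called macrophage-rich when the local concentration of CD68-positive
pixels reaches 40%. The neighbourhood over which "concentration" is
measured is a circular sliding window (default radius 0.1 mm), clipped
to the plaque region so border pixels are judged on available tissue
only. Analysis covers the entire plaque, not only fibrous caps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import GeometryError
from .quant import CCCResult, concordance_correlation

__all__ = [
    "CD68Mask",
    "MacrophageRichResult",
    "MacrophageComparison",
    "detect_macrophage_rich",
    "compare_macrophage",
]


@dataclass
class CD68Mask:
    """CD68-positive pixels restricted to a plaque region."""

    positives: np.ndarray
    plaque_region: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, bool)
        self.plaque_region = np.asarray(self.plaque_region, bool)
        if self.positives.shape != self.plaque_region.shape:
            raise GeometryError("CD68 and plaque grids must share the shape")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel_size_mm must be positive")
        if np.any(self.positives & ~self.plaque_region):
            raise GeometryError("CD68-positive pixels must lie within the plaque region")


@dataclass
class MacrophageRichResult:
    rich_mask: np.ndarray
    area_mm2: float
    window_radius_mm: float
    threshold: float


def _disk_kernel(radius_px: int) -> np.ndarray:
    r = np.arange(-radius_px, radius_px + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return (yy**2 + xx**2 <= radius_px**2).astype(np.int64)


def detect_macrophage_rich(
    cd68: CD68Mask, window_radius_mm: float = 0.1, threshold: float = 0.40
) -> MacrophageRichResult:
    """Threshold the local CD68-positive fraction within a circular window.

    A plaque pixel is macrophage-rich iff positives / plaque pixels within
    the window (clipped to the plaque region) is at least ``threshold``.
    With a window of one pixel this degenerates to the raw positive mask.
    """
    if window_radius_mm <= 0:
        raise GeometryError("window_radius_mm must be positive")
    if not 0 < threshold <= 1:
        raise GeometryError("threshold must lie in (0, 1]")
    if not cd68.plaque_region.any():
        raise GeometryError("empty plaque region")
    radius_px = max(1, int(round(window_radius_mm / cd68.pixel_size_mm)))
    kernel = _disk_kernel(radius_px)
    pos = ndimage.convolve(
        cd68.positives.astype(np.int64), kernel, mode="constant", cval=0
    )
    den = ndimage.convolve(
        cd68.plaque_region.astype(np.int64), kernel, mode="constant", cval=0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, pos / np.maximum(den, 1), 0.0)
    rich = cd68.plaque_region & (frac >= threshold - 1e-12)
    area = float(rich.sum()) * cd68.pixel_size_mm**2
    return MacrophageRichResult(rich, area, window_radius_mm, threshold)


@dataclass
class MacrophageComparison:
    total_hist_mm2: float
    total_ml_mm2: float
    ccc: CCCResult
    n_frames: int
    n_ml_missed: int  # frames where histology found macrophages but the classifier none


def compare_macrophage(
    hist_areas: Sequence[float], ml_areas: Sequence[float]
) -> MacrophageComparison:
    """Summed macrophage-rich areas and their concordance across frames."""
    a = np.asarray(hist_areas, float)
    b = np.asarray(ml_areas, float)
    if a.shape != b.shape or a.ndim != 1:
        raise GeometryError("paired per-frame area vectors required")
    if len(a) < 3:
        ccc = CCCResult(np.nan, np.nan, np.nan, np.nan, len(a))
    else:
        ccc = concordance_correlation(a, b)
    return MacrophageComparison(
        total_hist_mm2=float(a.sum()),
        total_ml_mm2=float(b.sum()),
        ccc=ccc,
        n_frames=len(a),
        n_ml_missed=int(np.count_nonzero((b == 0) & (a > 0))),
    )
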