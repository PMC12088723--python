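"""Contour and label-mask primitives shared by all pipeline stages.

A vessel cross-section is described by two closed polygonal contours —
the lumen border and the external elastic membrane (EEM) — in pixel
coordinates, plus an indexed tissue label mask on the same grid. Plaque
area is EEM area minus lumen area; plaque burden is plaque area as a
percentage of EEM area.

Coordinates are 0-based pixel indices (x = column, y = row); a pixel's
label applies to its full unit square. Polygon areas use the shoelace
formula; mask areas use pixel counts times pixel_size_mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .labels import DEFAULT_CODES, TISSUE_CODES

__all__ = [
    "GeometryError",
    "Contour",
    "FrameGeometry",
    "TissueLabelMask",
    "polygon_area",
    "plaque_area",
    "plaque_burden",
    "arc_length_parameterize",
    "radial_coordinates",
    "nearest_on_contour",
    "points_at_arclength",
    "outward_normals_at",
    "contains_points",
    "max_outward_eem_depth_mm",
]


class GeometryError(ValueError):
    """Invalid annotation geometry (degenerate or inconsistent contours)."""


def _signed_area_px(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class Contour:
    """Closed simple polygon in pixel units with a physical pixel size.

    Orientation is normalized to counter-clockwise (positive shoelace
    area) at construction; the start vertex is preserved because landmark
    arc-length positions refer to it.
    """

    def __init__(self, points: Iterable, pixel_size_mm: float):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("contour points must be an (N, 2) array")
        # drop an explicit closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError("a contour needs at least 3 distinct points")
        if not np.isfinite(pts).all():
            raise GeometryError("contour contains non-finite coordinates")
        if pixel_size_mm <= 0 or not np.isfinite(pixel_size_mm):
            raise GeometryError("pixel_size_mm must be positive")
        signed = _signed_area_px(pts)
        scale = float(np.ptp(pts, axis=0).max()) or 1.0
        if abs(signed) <= 1e-12 * scale * scale:
            raise GeometryError("degenerate contour: zero enclosed area")
        if signed < 0:  # reverse, keeping the start vertex first
            pts = np.concatenate([pts[:1], pts[1:][::-1]], axis=0)
        self.points = pts
        self.points.setflags(write=False)
        self.pixel_size_mm = float(pixel_size_mm)
        if not self.polygon.is_valid:
            raise GeometryError("contour polygon is self-intersecting")

    def __len__(self) -> int:
        return len(self.points)

    @cached_property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @cached_property
    def _closed_points(self) -> np.ndarray:
        return np.concatenate([self.points, self.points[:1]], axis=0)

    @cached_property
    def segment_lengths_px(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self._closed_points, axis=0), axis=1)

    @cached_property
    def cumulative_arclength_px(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths_px)])

    @property
    def perimeter_px(self) -> float:
        return float(self.cumulative_arclength_px[-1])

    @property
    def perimeter_mm(self) -> float:
        return self.perimeter_px * self.pixel_size_mm

    def area_px2(self) -> float:
        return abs(_signed_area_px(self.points))

    def with_start_vertex(self, index: int) -> "Contour":
        """Rotate the vertex order so ``index`` becomes the start vertex."""
        pts = np.roll(np.asarray(self.points), -int(index), axis=0)
        return Contour(pts, self.pixel_size_mm)


def polygon_area(contour: Contour) -> float:
    """Enclosed area in mm^2 (shoelace area times pixel_size_mm^2)."""
    return contour.area_px2() * contour.pixel_size_mm**2


def plaque_area(eem_area: float, lumen_area: float) -> float:
    """Plaque area = EEM area − lumen area, both in mm^2."""
    if lumen_area < 0 or eem_area < 0:
        raise GeometryError("areas must be non-negative")
    if lumen_area > eem_area + 1e-12 * max(1.0, eem_area):
        raise GeometryError(
            f"lumen area {lumen_area:g} exceeds EEM area {eem_area:g}: "
            "inconsistent annotation"
        )
    return max(eem_area - lumen_area, 0.0)


def plaque_burden(plaque_area_mm2: float, eem_area: float) -> float:
    """Plaque burden in percent: plaque area / EEM area × 100."""
    if eem_area <= 0:
        raise GeometryError("EEM area must be positive")
    if plaque_area_mm2 < 0 or plaque_area_mm2 > eem_area + 1e-9 * eem_area:
        raise GeometryError("plaque area must lie in [0, EEM area]")
    return float(np.clip(plaque_area_mm2 / eem_area * 100.0, 0.0, 100.0))


def points_at_arclength(contour: Contour, s: np.ndarray) -> np.ndarray:
    """Points on the contour at normalized arc-length positions ``s``."""
    s = np.atleast_1d(np.asarray(s, dtype=float)) % 1.0
    target = s * contour.perimeter_px
    cum = contour.cumulative_arclength_px
    closed = contour._closed_points
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    return np.stack([x, y], axis=-1)


def arc_length_parameterize(
    contour: Contour, n_samples: int
) -> tuple[Contour, np.ndarray]:
    """Resample a contour at ``n_samples`` points equally spaced in arc length.

    The first sample coincides with the stored start vertex; returned
    normalized arc lengths are k/n for k = 0..n-1.
    """
    if n_samples < 8:
        raise GeometryError("n_samples must be at least 8")
    s = np.arange(n_samples) / n_samples
    pts = points_at_arclength(contour, s)
    return Contour(pts, contour.pixel_size_mm), s


def outward_normals_at(contour: Contour, s: np.ndarray) -> np.ndarray:
    """Unit outward normals at normalized arc-length positions ``s``.

    Tangents are central differences on a dense uniform resampling; for a
    counter-clockwise contour the outward normal of tangent (tx, ty) is
    (ty, -tx).
    """
    n_dense = max(1024, 4 * len(contour))
    dense = points_at_arclength(contour, np.arange(n_dense) / n_dense)
    tang = np.roll(dense, -1, axis=0) - np.roll(dense, 1, axis=0)
    normals = np.stack([tang[:, 1], -tang[:, 0]], axis=-1)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals /= np.where(norms > 0, norms, 1.0)
    idx = np.rint(np.atleast_1d(np.asarray(s)) % 1.0 * n_dense).astype(int) % n_dense
    return normals[idx]


def contains_points(contour: Contour, points: np.ndarray) -> np.ndarray:
    """Vectorized strict-interior test for an array of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    poly = contour.polygon
    shapely.prepare(poly)
    return shapely.contains_xy(poly, pts[..., 0], pts[..., 1])


def radial_coordinates(point, lumen: Contour) -> tuple[float, float]:
    """Arc-length position and outward depth of a point relative to the lumen.

    Returns ``(s, d_mm)`` where ``s`` is the normalized arc length of the
    nearest lumen-contour point and ``d_mm`` the Euclidean distance to it in
    mm. Ties between equidistant segments are broken toward smaller ``s``.
    Points strictly inside the lumen are rejected (they belong to the lumen,
    not the plaque).
    """
    p = np.asarray(point, dtype=float)
    a = lumen.points
    b = np.roll(np.asarray(lumen.points), -1, axis=0)
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(
        np.einsum("ij,ij->i", p[None, :] - a, ab) / np.where(seg_len2 > 0, seg_len2, 1.0),
        0.0,
        1.0,
    )
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - p[None, :], proj - p[None, :])
    dmin = d2.min()
    d_px = float(np.sqrt(dmin))
    if d_px > 1e-9 and lumen.polygon.contains(Point(*p)):
        raise GeometryError("point lies strictly inside the lumen")
    # tie-break toward smaller arc length among (near-)equidistant segments
    tol = max(1e-12, 1e-9 * max(dmin, 1.0))
    cand = np.flatnonzero(d2 <= dmin + tol)
    cum = lumen.cumulative_arclength_px
    s_cand = (cum[cand] + t[cand] * lumen.segment_lengths_px[cand]) / lumen.perimeter_px
    s = float(np.min(s_cand) % 1.0)
    return s, d_px * lumen.pixel_size_mm


def nearest_on_contour(
    points: np.ndarray, contour: Contour, n_dense: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-point arc coordinates for many query points.

    A dense uniform arc-length resampling is indexed with a KD-tree, then
    the match is refined by exact projection onto the two segments adjacent
    to the nearest sample. Returns ``(s, d_px)`` arrays (normalized arc
    length and distance in pixels); works for points on either side of the
    contour.
    """
    pts = np.asarray(points, dtype=float)
    dense = points_at_arclength(contour, np.arange(n_dense) / n_dense)
    tree = cKDTree(dense)
    _, idx = tree.query(pts)
    # candidate segments: (idx-1 -> idx) and (idx -> idx+1)
    s_best = np.empty(len(pts))
    d2_best = np.full(len(pts), np.inf)
    for start in ((idx - 1) % n_dense, idx):
        a = dense[start]
        b = dense[(start + 1) % n_dense]
        ab = b - a
        len2 = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(
            np.einsum("ij,ij->i", pts - a, ab) / np.where(len2 > 0, len2, 1.0), 0.0, 1.0
        )
        proj = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", pts - proj, pts - proj)
        better = d2 < d2_best
        d2_best = np.where(better, d2, d2_best)
        s_best = np.where(better, (start + t) / n_dense, s_best)
    return s_best % 1.0, np.sqrt(d2_best)


@dataclass
class TissueLabelMask:
    """Per-pixel tissue class grid with registered label codes."""

    grid: np.ndarray
    pixel_size_mm: float
    codes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise GeometryError("mask grid must be 2-D")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel_size_mm must be positive")
        registered = set(self.codes.values())
        present = set(np.unique(self.grid).tolist())
        unknown = present - registered
        if unknown:
            raise GeometryError(f"unregistered label codes in mask: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def class_area_mm2(self, code: int) -> float:
        return float(np.count_nonzero(self.grid == code)) * self.pixel_size_mm**2

    def plaque_mask(self) -> np.ndarray:
        """Boolean grid of pixels labeled with any plaque tissue class."""
        return np.isin(self.grid, TISSUE_CODES)


@dataclass
class FrameGeometry:
    """Lumen and EEM contours for one cross-section of a pullback."""

    lumen: Contour
    eem: Contour
    frame_id: str = ""
    longitudinal_position_mm: float = 0.0

    def __post_init__(self) -> None:
        if not np.isclose(self.lumen.pixel_size_mm, self.eem.pixel_size_mm):
            raise GeometryError("lumen and EEM must share pixel_size_mm")
        tol = 1e-6 * max(self.eem.perimeter_px, 1.0)
        if not self.eem.polygon.buffer(tol).contains(self.lumen.polygon):
            raise GeometryError(
                f"frame {self.frame_id!r}: lumen polygon is not inside the EEM"
            )

    @property
    def pixel_size_mm(self) -> float:
        return self.lumen.pixel_size_mm

    def lumen_area_mm2(self) -> float:
        return polygon_area(self.lumen)

    def eem_area_mm2(self) -> float:
        return polygon_area(self.eem)

    def plaque_area_mm2(self) -> float:
        return plaque_area(self.eem_area_mm2(), self.lumen_area_mm2())


def max_outward_eem_depth_mm(geometry: FrameGeometry, n_dense: int = 1024) -> float:
    """Largest outward depth of the EEM border relative to the lumen, in mm."""
    eem_pts = points_at_arclength(geometry.eem, np.arange(n_dense) / n_dense)
    _, d_px = nearest_on_contour(eem_pts, geometry.lumen, n_dense=n_dense)
    return float(d_px.max()) * geometry.pixel_size_mm
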