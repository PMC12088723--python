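"""Warp an annotated histology section onto matched intravascular geometry.

Depressurized histology sections and pressurized in vivo frames of the
same cross-section differ in lumen shape and pixel size. The warp puts
them in correspondence through a shared band coordinate system anchored
to the lumen border: every plaque point is addressed by its normalized
arc-length position ``s`` along the lumen contour and its outward
physical depth ``d`` in mm. Expert landmark pairs on the two lumen
borders define a circular, strictly monotone piecewise-linear map between
the two arc-length parameterizations; depth is carried over unchanged
(physical radial scaling through the two pixel sizes), which encodes the
working assumption that plaque tissue is neither compressed nor
elongated between the two acquisitions.

The warp is evaluated inversely — for every imaging-frame pixel the
corresponding histology sample is pulled — so the output mask has no
gaps or overlaps even at concave lumen segments, where forward "strips"
would collide. Label transfer is nearest-neighbour (labels are
categorical) in band-coordinate space, with a small subpixel supersample
and majority vote to reduce quantisation error at class boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    Contour,
    FrameGeometry,
    GeometryError,
    TissueLabelMask,
    contains_points,
    max_outward_eem_depth_mm,
    nearest_on_contour,
)
from .labels import BACKGROUND, CA, FT, LUMEN, NC

__all__ = [
    "LandmarkError",
    "LandmarkCorrespondence",
    "ArcLengthMap",
    "build_arclength_map",
    "HistologyFrame",
    "ImagingFrame",
    "MatchedPair",
    "WarpedHistology",
    "warp_histology",
    "render_hybrid",
]


class LandmarkError(ValueError):
    """Invalid landmark correspondence (crossing or duplicate pairs)."""


@dataclass
class LandmarkCorrespondence:
    """Ordered (s_hist, s_img) arc-length landmark pairs on the two lumens."""

    pairs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
            raise LandmarkError("need at least 2 landmark pairs of (s_hist, s_img)")
        if np.any(arr < 0) or np.any(arr >= 1):
            raise LandmarkError("landmark arc lengths must lie in [0, 1)")
        self.pairs = arr
        # raises on crossings:
        build_arclength_map(self)


class ArcLengthMap:
    """Circular, strictly monotone piecewise-linear map s_img -> s_hist."""

    def __init__(self, s_img: np.ndarray, s_hist: np.ndarray):
        order = np.argsort(s_img)
        s_in = np.asarray(s_img, float)[order]
        s_out = np.asarray(s_hist, float)[order]
        if np.any(np.diff(s_in) <= 0):
            dup = int(np.flatnonzero(np.diff(s_in) <= 0)[0])
            raise LandmarkError(
                f"duplicate imaging arc-length at landmark pair {dup} (s_img={s_in[dup]:g})"
            )
        inc = np.diff(np.concatenate([s_out, s_out[:1]])) % 1.0
        if np.any(inc <= 0):
            bad = int(np.flatnonzero(inc <= 0)[0])
            raise LandmarkError(
                f"landmark pair {bad} crosses its neighbour: histology arc "
                "lengths must advance monotonically around the contour"
            )
        if not np.isclose(inc.sum(), 1.0):
            bad = int(np.argmax(inc))
            raise LandmarkError(
                f"landmark pairs cross (winding {inc.sum():g} != 1); "
                f"largest offending increment at pair {bad}"
            )
        # unwrapped output knots, extended by one wrapped knot on each side
        out_unwrapped = s_out[0] + np.concatenate([[0.0], np.cumsum(inc[:-1])])
        self._x = np.concatenate([s_in, [s_in[0] + 1.0]])
        self._y = np.concatenate([out_unwrapped, [out_unwrapped[0] + 1.0]])

    def __call__(self, s_img):
        s = np.asarray(s_img, dtype=float) % 1.0
        # shift into the covered period [x0, x0 + 1)
        shifted = self._x[0] + (s - self._x[0]) % 1.0
        out = np.interp(shifted, self._x, self._y) - (shifted - s)
        result = out % 1.0
        if np.isscalar(s_img) or np.ndim(s_img) == 0:
            return float(result)
        return result


def build_arclength_map(landmarks: LandmarkCorrespondence) -> ArcLengthMap:
    """Construct the imaging→histology arc-length map from landmark pairs."""
    pairs = np.asarray(landmarks.pairs, dtype=float)
    return ArcLengthMap(s_img=pairs[:, 1], s_hist=pairs[:, 0])


@dataclass
class HistologyFrame:
    geometry: FrameGeometry
    mask: TissueLabelMask
    cd68: Optional[np.ndarray] = None  # boolean CD68-positive grid, same shape

    def __post_init__(self) -> None:
        if self.cd68 is not None:
            self.cd68 = np.asarray(self.cd68, dtype=bool)
            if self.cd68.shape != self.mask.shape:
                raise GeometryError("CD68 mask shape must match the histology mask")


@dataclass
class ImagingFrame:
    geometry: FrameGeometry
    mask: TissueLabelMask
    modality: str = "NIRS-IVUS"  # "NIRS-IVUS" | "OCT"


@dataclass
class MatchedPair:
    """One histology section matched to one intravascular frame."""

    histology: HistologyFrame
    imaging: ImagingFrame
    landmarks: LandmarkCorrespondence
    frame_id: str = ""

    def __post_init__(self) -> None:
        for frame in (self.histology, self.imaging):
            if frame.geometry.pixel_size_mm != frame.mask.pixel_size_mm:
                raise GeometryError(
                    f"frame {self.frame_id!r}: contour and mask pixel sizes differ"
                )


@dataclass
class WarpedHistology:
    """Histology labels resampled onto the imaging-frame pixel grid."""

    mask: TissueLabelMask
    valid_region: np.ndarray
    strip_depth_mm: float

    def plaque_mask(self) -> np.ndarray:
        return self.valid_region & self.mask.plaque_mask()


def _band_embedding(s: np.ndarray, d_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Embed (arc length, depth) so Euclidean distance approximates band distance."""
    ang = 2.0 * np.pi * np.asarray(s, float)
    return np.stack(
        [radius_mm * np.cos(ang), radius_mm * np.sin(ang), np.asarray(d_mm, float)],
        axis=-1,
    )


_SUBSAMPLE_OFFSETS = np.array(
    [[-0.25, -0.25], [0.25, -0.25], [-0.25, 0.25], [0.25, 0.25]]
)


def warp_histology(
    pair: MatchedPair,
    strip_depth_mm: Optional[float] = None,
    angular_samples: int = 720,
    supersample: bool = True,
) -> WarpedHistology:
    """Pull histology labels onto the imaging pixel grid.

    For each imaging pixel in the plaque band (outward depth
    0 <= d <= strip_depth_mm from the imaging lumen) the source sample sits
    at histology band coordinates (map(s_img), d); the label is taken from
    the nearest histology pixel in band-coordinate space. Pixels whose
    source falls outside the histology image are marked invalid; pixels
    mapped beyond the histology EEM keep the histology background label
    (valid but not plaque). The default strip depth covers the whole
    imaging plaque: max outward EEM depth + 0.5 mm.
    """
    if strip_depth_mm is not None and strip_depth_mm <= 0:
        raise GeometryError("strip_depth_mm must be positive")
    img = pair.imaging
    hist = pair.histology
    h_img, w_img = img.mask.shape
    px_img = img.mask.pixel_size_mm
    px_hist = hist.mask.pixel_size_mm
    n_dense = max(int(angular_samples), 1024)

    if strip_depth_mm is None:
        strip_depth_mm = max_outward_eem_depth_mm(img.geometry) + 0.5

    yy, xx = np.mgrid[0:h_img, 0:w_img]
    coords = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
    inside_lumen = contains_points(img.geometry.lumen, coords).reshape(h_img, w_img)

    s_img_all, d_img_px = nearest_on_contour(coords, img.geometry.lumen, n_dense)
    d_img_mm = (d_img_px * px_img).reshape(h_img, w_img)
    s_img_all = s_img_all.reshape(h_img, w_img)
    band = (~inside_lumen) & (d_img_mm <= strip_depth_mm)

    arcmap = build_arclength_map(pair.landmarks)

    # histology band pixels keyed by their own (s, d) coordinates; only
    # pixels within strip depth of the lumen bounding box can be sources
    hy, hx = np.mgrid[0 : hist.mask.shape[0], 0 : hist.mask.shape[1]]
    hcoords = np.stack([hx.ravel(), hy.ravel()], axis=-1).astype(float)
    lpts = np.asarray(hist.geometry.lumen.points)
    margin_px = strip_depth_mm / px_hist + 5.0
    lo = lpts.min(axis=0) - margin_px
    hi = lpts.max(axis=0) + margin_px
    in_box = np.all((hcoords >= lo) & (hcoords <= hi), axis=1)
    box_idx = np.flatnonzero(in_box)
    hist_inside = contains_points(hist.geometry.lumen, hcoords[box_idx])
    source_idx = box_idx[~hist_inside]
    if len(source_idx) == 0:
        raise GeometryError("histology frame has no pixels outside the lumen")
    s_h, d_h_px = nearest_on_contour(hcoords[source_idx], hist.geometry.lumen, n_dense)
    radius_mm = hist.geometry.lumen.perimeter_mm / (2.0 * np.pi)
    tree = cKDTree(_band_embedding(s_h, d_h_px * px_hist, radius_mm))
    hist_labels = hist.mask.grid.ravel()[source_idx]

    # queries: band pixels, optionally supersampled 2x2 with majority vote
    band_flat = np.flatnonzero(band.ravel())
    max_key_dist = 3.0 * px_hist
    if supersample:
        offsets = _SUBSAMPLE_OFFSETS
    else:
        offsets = np.zeros((1, 2))
    votes = np.zeros((len(band_flat), len(offsets)), dtype=np.int64)
    vote_valid = np.zeros((len(band_flat), len(offsets)), dtype=bool)
    base_pts = coords[band_flat]
    for j, off in enumerate(offsets):
        pts = base_pts + off[None, :]
        s_q, d_q_px = nearest_on_contour(pts, img.geometry.lumen, n_dense)
        d_q_mm = np.maximum(d_q_px * px_img, 0.0)
        q = _band_embedding(arcmap(s_q), d_q_mm, radius_mm)
        dist, nn = tree.query(q)
        votes[:, j] = hist_labels[nn]
        vote_valid[:, j] = dist <= max_key_dist
    # majority vote over valid subsamples; ties -> smallest label code
    labels_out = np.full(len(band_flat), BACKGROUND, dtype=np.int64)
    valid_out = vote_valid.sum(axis=1) * 2 > len(offsets)
    if len(band_flat):
        masked = np.where(vote_valid, votes, -1)
        n_codes = int(max(hist_labels.max(initial=0), 1)) + 1
        counts = np.zeros((len(band_flat), n_codes), dtype=np.int16)
        for j in range(masked.shape[1]):
            col = masked[:, j]
            ok = col >= 0
            np.add.at(counts, (np.flatnonzero(ok), col[ok]), 1)
        labels_out = np.argmax(counts, axis=1)

    grid = np.full((h_img, w_img), BACKGROUND, dtype=np.int64)
    flat = grid.ravel()
    keep = valid_out
    flat[band_flat[keep]] = labels_out[keep]
    grid = flat.reshape(h_img, w_img)
    valid = np.zeros((h_img, w_img), dtype=bool)
    valid.ravel()[band_flat[keep]] = True

    warped_mask = TissueLabelMask(grid, px_img, codes=dict(hist.mask.codes))
    return WarpedHistology(mask=warped_mask, valid_region=valid, strip_depth_mm=float(strip_depth_mm))


#: fixed legend for hybrid overlays (RGB)
OVERLAY_PALETTE = {
    BACKGROUND: (0, 0, 0),
    LUMEN: (60, 60, 60),
    FT: (46, 139, 87),
    CA: (255, 255, 255),
    NC: (220, 38, 38),
}


def render_hybrid(pair: MatchedPair, warped: WarpedHistology) -> np.ndarray:
    """Deterministic RGB composite of imaging labels and warped histology.

    For visual inspection only; no downstream analysis depends on it.
    Imaging labels fill the base layer; warped histology tissue is alpha-
    blended on top at 50%.
    """
    if warped.mask.shape != pair.imaging.mask.shape:
        raise GeometryError("warped mask and imaging frame grid sizes differ")
    base = np.zeros((*pair.imaging.mask.shape, 3), dtype=float)
    for code, rgb in OVERLAY_PALETTE.items():
        base[pair.imaging.mask.grid == code] = rgb
    over = base.copy()
    tissue = warped.plaque_mask()
    for code in (FT, CA, NC):
        sel = tissue & (warped.mask.grid == code)
        over[sel] = OVERLAY_PALETTE[code]
    blended = 0.5 * base + 0.5 * over
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
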