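"""Synthetic matched histology/intravascular pairs with known ground truth.

Stands in for cadaveric datasets: every frame is generated from an
analytic vessel description, so co-registration accuracy and agreement
statistics can be validated against closed-form truth with no data
download.

The model, in lumen band coordinates (polar angle θ about the vessel
centre, outward depth d from the lumen border):

* the pressurized lumen is star-shaped, r(θ) = R·(1 + Σ a_k cos(kθ+φ_k))
  with low-order harmonics;
* the vessel wall (plaque) is fibrotic tissue of thickness
  t(θ) = t0 + t1·cos(θ+φ), with elliptical calcific and necrotic-core
  inclusions placed in (θ, d) band coordinates — their physical areas are
  then available by 1-D quadrature (∬(r(θ)+d) dθ dd), which supplies the
  conservation oracles. Where sampled regions would collide, the calcific
  class takes precedence, mirroring the histology annotation rule;
* the depressurized histology counterpart collapses the lumen radially
  (optionally asymmetrically) while tissue keeps its physical outward
  depth — the same incompressibility assumption the warping method makes.
  An optional global scale shrinks tissue depths too, deliberately
  violating that assumption for sensitivity studies. Histology is
  rendered at its own (finer) pixel size, and true landmark
  correspondences are emitted at matching polar angles;
* the simulated classifier output relabels tissue through a row-
  stochastic misclassification matrix realized as a spatially correlated
  random field (each pixel's marginal relabeling law is exactly the
  configured row; errors are patchy, as real classifier errors are),
  jitters class boundaries with a smooth random displacement field, can
  bias the EEM border radially (emulating ultrasound overestimation or
  light-based underestimation), and in OCT mode truncates the EEM at a
  penetration depth and calls deeper tissue necrotic core (signal
  attenuation).

Randomness is reproducible regardless of generation order: frame i of a
cohort seeded with s draws from ``SeedSequence((s, i))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .coregister import (
    HistologyFrame,
    ImagingFrame,
    LandmarkCorrespondence,
    MatchedPair,
)
from .geometry import (
    Contour,
    FrameGeometry,
    GeometryError,
    TissueLabelMask,
    nearest_on_contour,
    outward_normals_at,
    points_at_arclength,
)
from .labels import BACKGROUND, CA, FT, LUMEN, NC

__all__ = [
    "SyntheticConfig",
    "Inclusion",
    "VesselTruth",
    "TruthRecord",
    "SyntheticPair",
    "generate_vessel",
    "degrade_to_histology",
    "simulate_ml_estimation",
    "generate_cohort",
    "NIRS_LIKE_ERROR_RATES",
    "OCT_LIKE_ERROR_RATES",
]

_IDENTITY = np.eye(3)

#: qualitative error profiles for demonstration scenarios: fibrotic mostly
#: correct; necrotic core frequently read as fibrotic; OCT additionally
#: confuses necrotic core in both directions.
NIRS_LIKE_ERROR_RATES = np.array(
    [[0.97, 0.01, 0.02], [0.30, 0.66, 0.04], [0.63, 0.02, 0.35]]
)
OCT_LIKE_ERROR_RATES = np.array(
    [[0.83, 0.01, 0.16], [0.32, 0.46, 0.22], [0.66, 0.00, 0.34]]
)

_QUAD_N = 8192  # θ-grid size for analytic quadrature


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized coronary cross-section (EEM area around
    12 mm^2, plaque burden around 50%) with three calcific and three
    necrotic-core inclusions per frame and a 20% linear histology
    shrinkage, imaged at 20 µm (catheter frame) and 8 µm (histology).
    """

    # grids and resolutions
    grid_size_img: int = 384
    pixel_size_img_mm: float = 0.02
    pixel_size_hist_mm: float = 0.008
    grid_size_hist: Optional[int] = None  # default: cover the imaging field of view

    # vessel geometry
    lumen_radius_mm: float = 1.4
    lumen_radius_sd_mm: float = 0.15
    lumen_harmonic_orders: tuple[int, ...] = (2, 3, 4)
    lumen_harmonic_amplitudes: tuple[float, ...] = (0.06, 0.04, 0.02)
    eem_thickness_range_mm: tuple[float, float] = (0.45, 0.75)
    eem_thickness_harmonic_mm: float = 0.08

    # inclusions
    ca_count: int = 3
    nc_count: int = 3
    inclusion_area_range_mm2: tuple[float, float] = (0.10, 0.30)
    inclusion_depth_semi_range_mm: tuple[float, float] = (0.10, 0.18)
    inclusion_margin_mm: float = 0.05
    inclusion_gap_rad: float = 0.08
    max_retries: int = 200

    # histology degradation
    shrinkage_factor: float = 0.8
    shrink_asymmetry: float = 0.05
    histology_global_scale: float = 1.0

    # simulated classifier
    modality: str = "NIRS-IVUS"
    misclassification: np.ndarray = field(default_factory=lambda: _IDENTITY.copy())
    error_correlation_length_mm: float = 0.08  # 1/e autocorrelation distance
    boundary_noise_sd_mm: float = 0.03
    ml_eem_radial_bias_mm: float = 0.0
    oct_eem_truncation_depth_mm: Optional[float] = None
    oct_attenuation_depth_mm: Optional[float] = None

    # landmarks and optional CD68 staining
    landmark_count: int = 16
    include_cd68: bool = False
    cd68_focus_count: int = 3
    cd68_focus_radius_mm: float = 0.25
    cd68_focus_density: float = 0.7
    cd68_background_density: float = 0.02

    def __post_init__(self) -> None:
        self.misclassification = np.asarray(self.misclassification, float)
        if self.misclassification.shape != (3, 3) or np.any(self.misclassification < 0):
            raise GeometryError("misclassification must be a non-negative 3x3 matrix")
        if not np.allclose(self.misclassification.sum(axis=1), 1.0):
            raise GeometryError("misclassification rows must sum to 1")
        if not 0 < self.shrinkage_factor <= 1:
            raise GeometryError("shrinkage factor must lie in (0, 1]")
        for name in (
            "pixel_size_img_mm",
            "pixel_size_hist_mm",
            "lumen_radius_mm",
            "error_correlation_length_mm",
            "histology_global_scale",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.grid_size_hist is None:
            fov = self.grid_size_img * self.pixel_size_img_mm
            self.grid_size_hist = int(np.ceil(fov / self.pixel_size_hist_mm))


@dataclass
class Inclusion:
    """Elliptical inclusion in (θ, depth) band coordinates."""

    code: int  # CA or NC
    theta0: float  # centre angle, radians
    alpha: float  # angular semi-width, radians
    d0: float  # centre depth, mm
    beta: float  # depth semi-height, mm

    def membership(self, theta: np.ndarray, d: np.ndarray) -> np.ndarray:
        dtheta = (theta - self.theta0 + np.pi) % (2 * np.pi) - np.pi
        return (dtheta / self.alpha) ** 2 + ((d - self.d0) / self.beta) ** 2 <= 1.0


@dataclass
class TruthRecord:
    """Analytic per-frame truth for oracles and recovery tests."""

    frame_id: str
    truth_lumen_area_mm2: float
    truth_eem_area_mm2: float
    truth_plaque_area_mm2: float
    truth_ft_area_mm2: float
    truth_ca_area_mm2: float
    truth_nc_area_mm2: float
    hist_lumen_area_mm2: float
    hist_eem_area_mm2: float
    hist_plaque_area_mm2: float
    hist_ft_area_mm2: float
    hist_ca_area_mm2: float
    hist_nc_area_mm2: float
    ml_eem_area_mm2: float
    ml_eem_bias_area_mm2: float
    misclassification: np.ndarray
    shrinkage_factor: float
    global_scale: float
    landmark_pairs: np.ndarray


@dataclass
class VesselTruth:
    """Analytic description of one generated cross-section."""

    config: SyntheticConfig
    frame_id: str
    radius_mm: float
    harmonic_orders: np.ndarray
    harmonic_amps_mm: np.ndarray
    harmonic_phases: np.ndarray
    thickness_base_mm: float
    thickness_harmonic_mm: float
    thickness_phase: float
    inclusions: list[Inclusion]
    shrink_phase: float = 0.0
    record: Optional[TruthRecord] = None

    # --- analytic geometry -------------------------------------------------
    def r_lumen(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        r = np.full(theta.shape, self.radius_mm)
        for k, a, p in zip(self.harmonic_orders, self.harmonic_amps_mm, self.harmonic_phases):
            r = r + a * np.cos(k * theta + p)
        return r

    def thickness(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        return self.thickness_base_mm + self.thickness_harmonic_mm * np.cos(
            theta + self.thickness_phase
        )

    def shrink_profile(self, theta: np.ndarray) -> np.ndarray:
        cfg = self.config
        return cfg.shrinkage_factor * (
            1.0 + cfg.shrink_asymmetry * np.cos(np.asarray(theta, float) + self.shrink_phase)
        )

    def r_lumen_hist(self, theta: np.ndarray) -> np.ndarray:
        return self.config.histology_global_scale * self.shrink_profile(theta) * self.r_lumen(theta)

    def label_banded(self, theta: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Tissue label at band coordinates of the pressurized frame."""
        theta = np.asarray(theta, float)
        d = np.asarray(d, float)
        t = self.thickness(theta)
        out = np.full(theta.shape, BACKGROUND, dtype=np.int64)
        out[d < 0] = LUMEN
        in_wall = (d >= 0) & (d <= t)
        out[in_wall] = FT
        for code in (NC, CA):  # Ca last: precedence where regions collide
            for inc in self.inclusions:
                if inc.code != code:
                    continue
                member = in_wall & inc.membership(theta, d)
                out[member] = code
        return out

    # --- analytic areas ----------------------------------------------------
    def _theta_grid(self) -> np.ndarray:
        return np.linspace(0.0, 2 * np.pi, _QUAD_N, endpoint=False)

    def lumen_area(self) -> float:
        th = self._theta_grid()
        return float(np.mean(0.5 * self.r_lumen(th) ** 2) * 2 * np.pi)

    def eem_area(self) -> float:
        th = self._theta_grid()
        r = self.r_lumen(th) + self.thickness(th)
        return float(np.mean(0.5 * r**2) * 2 * np.pi)

    def inclusion_area(self, inc: Inclusion, hist: bool = False) -> float:
        """Physical area of one inclusion by 1-D quadrature over θ."""
        g = self.config.histology_global_scale if hist else 1.0
        th = np.linspace(inc.theta0 - inc.alpha, inc.theta0 + inc.alpha, 2049)
        w = np.sqrt(np.clip(1.0 - ((th - inc.theta0) / inc.alpha) ** 2, 0.0, 1.0))
        r = self.r_lumen_hist(th) if hist else self.r_lumen(th)
        integrand = 2.0 * g * inc.beta * w * (r + g * inc.d0)
        return float(np.trapezoid(integrand, th))

    def class_areas(self, hist: bool = False) -> dict[int, float]:
        if hist:
            th = self._theta_grid()
            r_in = self.r_lumen_hist(th)
            g = self.config.histology_global_scale
            r_out = r_in + g * self.thickness(th)
            plaque = float(np.mean(0.5 * (r_out**2 - r_in**2)) * 2 * np.pi)
        else:
            plaque = self.eem_area() - self.lumen_area()
        ca = sum(self.inclusion_area(i, hist) for i in self.inclusions if i.code == CA)
        nc = sum(self.inclusion_area(i, hist) for i in self.inclusions if i.code == NC)
        return {FT: plaque - ca - nc, CA: ca, NC: nc, -1: plaque}

    def hist_lumen_area(self) -> float:
        th = self._theta_grid()
        return float(np.mean(0.5 * self.r_lumen_hist(th) ** 2) * 2 * np.pi)

    def hist_eem_area(self) -> float:
        th = self._theta_grid()
        g = self.config.histology_global_scale
        r = self.r_lumen_hist(th) + g * self.thickness(th)
        return float(np.mean(0.5 * r**2) * 2 * np.pi)

    def ml_eem_area(self) -> float:
        th = self._theta_grid()
        r = self._r_eem_ml(th)
        return float(np.mean(0.5 * r**2) * 2 * np.pi)

    def _r_eem_ml(self, theta: np.ndarray) -> np.ndarray:
        cfg = self.config
        r_l = self.r_lumen(theta)
        r_e = r_l + self.thickness(theta)
        r = r_e + cfg.ml_eem_radial_bias_mm
        if cfg.modality == "OCT" and cfg.oct_eem_truncation_depth_mm is not None:
            r = np.minimum(r, r_l + cfg.oct_eem_truncation_depth_mm)
        return np.maximum(r, r_l + 0.05)

    # --- rasterisation helpers ---------------------------------------------
    def _grid_polar(self, n: int, px: float) -> tuple[np.ndarray, np.ndarray]:
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        dx = (xx - c) * px
        dy = (yy - c) * px
        theta = np.arctan2(dy, dx) % (2 * np.pi)
        rho = np.hypot(dx, dy)
        return theta, rho

    def _contour_from_radius(self, radius_fn, n: int, px: float, n_vertices: int = 720) -> Contour:
        c = (n - 1) / 2.0
        th = np.arange(n_vertices) * 2 * np.pi / n_vertices
        r_px = radius_fn(th) / px
        pts = np.stack([c + r_px * np.cos(th), c + r_px * np.sin(th)], axis=-1)
        return Contour(pts, px)

    def render_truth_mask(self) -> TissueLabelMask:
        cfg = self.config
        theta, rho = self._grid_polar(cfg.grid_size_img, cfg.pixel_size_img_mm)
        d = rho - self.r_lumen(theta)
        return TissueLabelMask(self.label_banded(theta, d), cfg.pixel_size_img_mm)

    def imaging_geometry(self) -> FrameGeometry:
        cfg = self.config
        lumen = self._contour_from_radius(self.r_lumen, cfg.grid_size_img, cfg.pixel_size_img_mm)
        eem = self._contour_from_radius(
            lambda th: self.r_lumen(th) + self.thickness(th),
            cfg.grid_size_img,
            cfg.pixel_size_img_mm,
        )
        return FrameGeometry(lumen, eem, frame_id=self.frame_id)

    def ml_geometry(self) -> FrameGeometry:
        cfg = self.config
        lumen = self._contour_from_radius(self.r_lumen, cfg.grid_size_img, cfg.pixel_size_img_mm)
        eem = self._contour_from_radius(self._r_eem_ml, cfg.grid_size_img, cfg.pixel_size_img_mm)
        return FrameGeometry(lumen, eem, frame_id=self.frame_id)


@dataclass
class SyntheticPair:
    pair: MatchedPair
    truth: VesselTruth


def _sample_inclusions(truth: VesselTruth, rng: np.random.Generator) -> None:
    cfg = truth.config
    counts = [(CA, cfg.ca_count), (NC, cfg.nc_count)]
    taken: list[tuple[float, float]] = []  # (theta0, halfwidth incl. gap)

    def overlaps(theta0: float, half: float) -> bool:
        for t0, h in taken:
            dt = abs((theta0 - t0 + np.pi) % (2 * np.pi) - np.pi)
            if dt < half + h:
                return True
        return False

    for code, count in counts:
        for _ in range(count):
            placed = False
            for _ in range(cfg.max_retries):
                theta0 = float(rng.uniform(0, 2 * np.pi))
                t_local = float(truth.thickness(theta0))
                margin = cfg.inclusion_margin_mm
                beta_max = (t_local - 2 * margin) / 2.0
                b_lo, b_hi = cfg.inclusion_depth_semi_range_mm
                if beta_max < b_lo:
                    continue
                area = float(rng.uniform(*cfg.inclusion_area_range_mm2))
                # aspect control: keep ellipses roughly 2:1 (arc:depth) so
                # they stay placeable around the circumference
                beta = float(np.clip(np.sqrt(area / (2 * np.pi)), b_lo, min(b_hi, beta_max)))
                d0 = float(rng.uniform(margin + beta, t_local - margin - beta))
                alpha = area / (np.pi * beta) / (float(truth.r_lumen(theta0)) + d0)
                if alpha >= np.pi / 2:
                    continue
                if overlaps(theta0, alpha + cfg.inclusion_gap_rad):
                    continue
                taken.append((theta0, alpha + cfg.inclusion_gap_rad))
                truth.inclusions.append(Inclusion(code, theta0, alpha, d0, beta))
                placed = True
                break
            if not placed:
                raise GeometryError(
                    "could not place all inclusions without overlap; reduce counts "
                    "or sizes"
                )


def generate_vessel(
    config: SyntheticConfig, seed, frame_id: str = "frame-000"
) -> tuple[ImagingFrame, VesselTruth]:
    """Sample one pressurized ground-truth cross-section.

    Returns the rasterized imaging frame (truth labels, truth contours) and
    the analytic description; ``truth.record`` carries the analytic areas.
    Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    radius = float(
        np.clip(
            rng.normal(cfg.lumen_radius_mm, cfg.lumen_radius_sd_mm),
            0.6 * cfg.lumen_radius_mm,
            1.5 * cfg.lumen_radius_mm,
        )
    )
    amps = radius * np.asarray(cfg.lumen_harmonic_amplitudes, float)
    phases = rng.uniform(0, 2 * np.pi, size=len(amps))
    t0 = float(rng.uniform(*cfg.eem_thickness_range_mm))
    truth = VesselTruth(
        config=cfg,
        frame_id=frame_id,
        radius_mm=radius,
        harmonic_orders=np.asarray(cfg.lumen_harmonic_orders, int),
        harmonic_amps_mm=amps,
        harmonic_phases=phases,
        thickness_base_mm=t0,
        thickness_harmonic_mm=min(cfg.eem_thickness_harmonic_mm, 0.45 * t0),
        thickness_phase=float(rng.uniform(0, 2 * np.pi)),
        inclusions=[],
        shrink_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    _sample_inclusions(truth, rng)
    mask = truth.render_truth_mask()
    geometry = truth.imaging_geometry()
    areas = truth.class_areas()
    hist_areas = truth.class_areas(hist=True)
    truth.record = TruthRecord(
        frame_id=frame_id,
        truth_lumen_area_mm2=truth.lumen_area(),
        truth_eem_area_mm2=truth.eem_area(),
        truth_plaque_area_mm2=areas[-1],
        truth_ft_area_mm2=areas[FT],
        truth_ca_area_mm2=areas[CA],
        truth_nc_area_mm2=areas[NC],
        hist_lumen_area_mm2=truth.hist_lumen_area(),
        hist_eem_area_mm2=truth.hist_eem_area(),
        hist_plaque_area_mm2=hist_areas[-1],
        hist_ft_area_mm2=hist_areas[FT],
        hist_ca_area_mm2=hist_areas[CA],
        hist_nc_area_mm2=hist_areas[NC],
        ml_eem_area_mm2=truth.ml_eem_area(),
        ml_eem_bias_area_mm2=truth.ml_eem_area() - truth.eem_area(),
        misclassification=cfg.misclassification.copy(),
        shrinkage_factor=cfg.shrinkage_factor,
        global_scale=cfg.histology_global_scale,
        landmark_pairs=np.zeros((0, 2)),
    )
    return ImagingFrame(geometry, mask, modality=cfg.modality), truth


def _arc_fraction_tables(truth: VesselTruth, n: int = 4096):
    """Dense θ → normalized arc-length tables for both lumen contours."""
    th = np.linspace(0.0, 2 * np.pi, n + 1)

    def table(radius_fn):
        r = radius_fn(th)
        x = r * np.cos(th)
        y = r * np.sin(th)
        seg = np.hypot(np.diff(x), np.diff(y))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum / cum[-1]

    return th, table(truth.r_lumen), table(truth.r_lumen_hist)


def degrade_to_histology(
    truth: VesselTruth, seed=None
) -> tuple[HistologyFrame, LandmarkCorrespondence]:
    """Produce the depressurized histology counterpart plus true landmarks.

    The lumen collapses radially by the (optionally asymmetric) shrinkage
    profile; tissue keeps its physical outward depth (scaled by the global
    factor when one is configured) and is resampled onto the finer
    histology grid. Landmarks pair the two lumen arc-length
    parameterizations at equally spaced polar angles.
    """
    cfg = truth.config
    g = cfg.histology_global_scale
    n_h = int(cfg.grid_size_hist)
    px_h = cfg.pixel_size_hist_mm

    hist_lumen = truth._contour_from_radius(truth.r_lumen_hist, n_h, px_h)
    hist_eem = truth._contour_from_radius(
        lambda th: truth.r_lumen_hist(th) + g * truth.thickness(th), n_h, px_h
    )
    hist_geom = FrameGeometry(hist_lumen, hist_eem, frame_id=truth.frame_id)

    th_tab, s_img_tab, s_hist_tab = _arc_fraction_tables(truth)

    # band coordinates of every histology pixel w.r.t. the collapsed lumen
    yy, xx = np.mgrid[0:n_h, 0:n_h]
    c = (n_h - 1) / 2.0
    pts = np.stack([xx.ravel().astype(float), yy.ravel().astype(float)], axis=-1)
    rho_mm = np.hypot(pts[:, 0] - c, pts[:, 1] - c) * px_h
    theta_px = np.arctan2(pts[:, 1] - c, pts[:, 0] - c) % (2 * np.pi)
    inside = rho_mm < truth.r_lumen_hist(theta_px)
    # pixels beyond the histology EEM (plus margin) are background a priori
    th_dense = np.linspace(0, 2 * np.pi, 1024)
    r_max = float(np.max(truth.r_lumen_hist(th_dense) + g * truth.thickness(th_dense)))
    near = ~inside & (rho_mm <= r_max + 0.05)

    s_h, d_h_px = nearest_on_contour(pts[near], hist_lumen, n_dense=4096)
    d_h_mm = d_h_px * px_h
    # s_hist -> θ -> s_img through the true (polar-angle) correspondence
    theta_of_s = np.interp(s_h, s_hist_tab, th_tab)
    s_i = np.interp(theta_of_s, th_tab, s_img_tab)

    img_lumen = truth.imaging_geometry().lumen
    base = points_at_arclength(img_lumen, s_i)
    normals = outward_normals_at(img_lumen, s_i)
    src = base + (d_h_mm / g / cfg.pixel_size_img_mm)[:, None] * normals

    c_img = (cfg.grid_size_img - 1) / 2.0
    src_theta = np.arctan2(src[:, 1] - c_img, src[:, 0] - c_img) % (2 * np.pi)
    src_rho = np.hypot(src[:, 0] - c_img, src[:, 1] - c_img) * cfg.pixel_size_img_mm
    labels = truth.label_banded(src_theta, src_rho - truth.r_lumen(src_theta))
    labels[labels == LUMEN] = FT  # folded samples at the lumen border stay tissue

    flat = np.full(n_h * n_h, BACKGROUND, dtype=np.int64)
    flat[inside] = LUMEN
    flat[np.flatnonzero(near)] = labels
    grid = flat.reshape(n_h, n_h)

    mask = TissueLabelMask(grid, px_h)

    k = cfg.landmark_count
    th_land = np.arange(k) * 2 * np.pi / k
    pairs = np.stack(
        [np.interp(th_land, th_tab, s_hist_tab), np.interp(th_land, th_tab, s_img_tab)],
        axis=-1,
    ) % 1.0
    landmarks = LandmarkCorrespondence(pairs)
    if truth.record is not None:
        truth.record.landmark_pairs = np.asarray(pairs)

    cd68 = None
    if cfg.include_cd68:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed if seed is not None else 0)
        )
        cd68 = _simulate_cd68(mask, cfg, rng)
    return HistologyFrame(hist_geom, mask, cd68=cd68), landmarks


def _simulate_cd68(
    mask: TissueLabelMask, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """CD68-positive pixels: dense foci plus sparse background staining."""
    plaque = mask.plaque_mask()
    pos = rng.random(mask.shape) < cfg.cd68_background_density
    rows, cols = np.nonzero(plaque)
    if len(rows):
        r_px = cfg.cd68_focus_radius_mm / mask.pixel_size_mm
        for _ in range(cfg.cd68_focus_count):
            i = int(rng.integers(len(rows)))
            cy, cx = rows[i], cols[i]
            yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
            focus = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
            pos |= focus & (rng.random(mask.shape) < cfg.cd68_focus_density)
    return pos & plaque


def _correlated_uniform_field(
    shape: tuple[int, int], corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field with (approximately) uniform [0,1) marginals."""
    # corr_px is the 1/e decay distance of the field autocorrelation; the
    # Gaussian smoothing kernel that produces it has sigma = corr_px / 2
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=max(corr_px / 2.0, 1e-6), mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.full(shape, 0.5)
    return stats.norm.cdf((smooth - smooth.mean()) / sd)


def simulate_ml_estimation(truth: VesselTruth, seed) -> ImagingFrame:
    """Simulated classifier output for the pressurized frame.

    Misclassification is applied as a per-class correlated random field
    whose per-pixel marginal law equals the configured matrix row; then
    boundaries are jittered by a smooth displacement field; then the EEM
    bias, and in OCT mode penetration truncation/attenuation, reshape the
    visible plaque. Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = truth.config
    n = cfg.grid_size_img
    px = cfg.pixel_size_img_mm
    grid = truth.render_truth_mask().grid.copy()
    theta, rho = truth._grid_polar(n, px)
    d = rho - truth.r_lumen(theta)
    t = truth.thickness(theta)

    corr_px = cfg.error_correlation_length_mm / px
    codes = np.array([FT, CA, NC])
    true_grid = grid.copy()  # each pixel is relabeled from its TRUE class once
    for i, code in enumerate(codes):
        row = cfg.misclassification[i]
        # field drawn even for identity rows so the stream is row-stable
        u = _correlated_uniform_field((n, n), corr_px, rng)
        if np.allclose(row, np.eye(3)[i]):
            continue
        sel = true_grid == code
        if not sel.any():
            continue
        idx = np.minimum(np.searchsorted(np.cumsum(row), u[sel], side="right"), 2)
        grid[sel] = codes[idx]

    if cfg.boundary_noise_sd_mm > 0:
        sigma_px = cfg.boundary_noise_sd_mm / px
        disp = []
        for _ in range(2):
            f = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0, mode="wrap")
            f = f / (f.std() or 1.0) * sigma_px
            disp.append(f)
        yy, xx = np.mgrid[0:n, 0:n]
        sampled = ndimage.map_coordinates(
            grid, [yy + disp[0], xx + disp[1]], order=0, mode="nearest"
        )
        in_wall = (d >= 0) & (d <= t)
        keep_tissue = in_wall & np.isin(sampled, codes)
        grid[keep_tissue] = sampled[keep_tissue]

    # EEM bias / OCT truncation reshape the visible plaque
    r_e_ml = truth._r_eem_ml(theta)
    r_e_true = truth.r_lumen(theta) + t
    inside_ml = (d >= 0) & (rho <= r_e_ml)
    grid[(rho > r_e_true) & inside_ml] = FT  # extra ring read as fibrotic
    grid[(d >= 0) & (rho > r_e_ml)] = BACKGROUND
    if cfg.modality == "OCT" and cfg.oct_attenuation_depth_mm is not None:
        grid[inside_ml & (d > cfg.oct_attenuation_depth_mm)] = NC
    grid[d < 0] = LUMEN

    return ImagingFrame(
        geometry=truth.ml_geometry(),
        mask=TissueLabelMask(grid, px),
        modality=cfg.modality,
    )


def generate_cohort(
    config: SyntheticConfig, n_frames: int, seed: int
) -> list[SyntheticPair]:
    """Independent matched pairs with longitudinal spacing of 0.5 mm.

    Frame i draws from ``SeedSequence((seed, i))``, so any subset of the
    cohort is reproducible regardless of generation order.
    """
    if n_frames < 1:
        raise GeometryError("n_frames must be at least 1")
    out: list[SyntheticPair] = []
    for i in range(n_frames):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), i)))
        frame_id = f"frame-{i:03d}"
        imaging, truth = generate_vessel(config, rng, frame_id=frame_id)
        hist, landmarks = degrade_to_histology(truth, seed=rng)
        ml = simulate_ml_estimation(truth, rng)
        imaging_for_pair = ImagingFrame(ml.geometry, ml.mask, modality=ml.modality)
        imaging_for_pair.geometry.longitudinal_position_mm = i * 0.5
        hist.geometry.longitudinal_position_mm = i * 0.5
        pair = MatchedPair(
            histology=hist,
            imaging=imaging_for_pair,
            landmarks=landmarks,
            frame_id=frame_id,
        )
        out.append(SyntheticPair(pair=pair, truth=truth))
    return out
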