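import numpy as np
import pytest
from hypothesis import settings

from plaqueval.coregister import (
    HistologyFrame,
    ImagingFrame,
    LandmarkCorrespondence,
    MatchedPair,
)
from plaqueval.geometry import Contour, FrameGeometry, TissueLabelMask
from plaqueval.labels import BACKGROUND, CA, FT, LUMEN, NC
from plaqueval.synthetic import SyntheticConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def circle_contour(radius_px: float, pixel_size_mm: float = 1.0, n: int = 360,
                   center=(0.0, 0.0)) -> Contour:
    th = np.arange(n) * 2 * np.pi / n
    pts = np.stack(
        [center[0] + radius_px * np.cos(th), center[1] + radius_px * np.sin(th)], axis=-1
    )
    return Contour(pts, pixel_size_mm)


def annulus_frame(px: float, r_lumen=1.0, r_ca=(1.2, 1.5), r_eem=1.6, fov=3.7):
    """Concentric-circle frame: FT wall with one Ca ring, analytic truth."""
    n = int(np.ceil(fov / px))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(xx - c, yy - c) * px
    grid = np.full((n, n), BACKGROUND, np.int64)
    grid[rho < r_eem] = FT
    grid[(rho >= r_ca[0]) & (rho <= r_ca[1])] = CA
    grid[rho < r_lumen] = LUMEN
    th = np.arange(720) * 2 * np.pi / 720

    def circ(r):
        return Contour(
            np.stack([c + r / px * np.cos(th), c + r / px * np.sin(th)], -1), px
        )

    return FrameGeometry(circ(r_lumen), circ(r_eem)), TissueLabelMask(grid, px)


IDENTITY_LANDMARKS = LandmarkCorrespondence(
    np.array([[0.0, 0.0], [0.25, 0.25], [0.5, 0.5], [0.75, 0.75]])
)


def make_pair(hist, imaging, landmarks=IDENTITY_LANDMARKS, frame_id="t"):
    return MatchedPair(
        histology=HistologyFrame(*hist),
        imaging=ImagingFrame(*imaging),
        landmarks=landmarks,
        frame_id=frame_id,
    )


def small_config(**overrides) -> SyntheticConfig:
    """Reduced-resolution study conditions for fast unit tests."""
    base = dict(
        grid_size_img=192,
        pixel_size_img_mm=0.04,
        pixel_size_hist_mm=0.02,
        landmark_count=12,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def shrunken_pair():
    """One default-shrinkage matched pair with a perfect classifier."""
    cfg = small_config(boundary_noise_sd_mm=0.0)
    return generate_cohort(cfg, 1, 5)[0]


@pytest.fixture(scope="session")
def identity_pair():
    """Same physical frame on both sides: no shrinkage, equal pixels."""
    cfg = SyntheticConfig(
        shrinkage_factor=1.0,
        shrink_asymmetry=0.0,
        pixel_size_hist_mm=0.02,
        boundary_noise_sd_mm=0.0,
    )
    return generate_cohort(cfg, 1, 7)[0]
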