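import numpy as np
import pytest

from plaqueval.agreement import (
    ConfusionMatrix,
    area_level_confusion,
    error_vs_burden,
    extract_rois,
    metrics_from_confusion,
    missed_tissue_report,
    overlap_analysis,
    region_level_confusion,
)
from plaqueval.coregister import WarpedHistology
from plaqueval.geometry import GeometryError, TissueLabelMask
from plaqueval.labels import BACKGROUND, CA, FT, NC, TISSUE_CODES
from plaqueval.quant import StatError

from .conftest import circle_contour


def warped_from_grid(grid, px=0.1):
    grid = np.asarray(grid, np.int64)
    return WarpedHistology(
        TissueLabelMask(grid, px), np.ones_like(grid, bool), strip_depth_mm=5.0
    )


class TestOverlap:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        r = overlap_analysis(m, m, 0.1)
        assert r.overlap_pct == 100.0 and r.hist_only_pct == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5] = True
        b[6:] = True
        r = overlap_analysis(a, b, 0.1)
        assert r.overlap_pct == 0.0 and r.hist_only_pct == 100.0
        assert r.ml_only_pct == 100.0

    def test_half_overlap(self):
        a = np.zeros((10, 10), bool)
        a[:, :8] = True
        b = np.zeros((10, 10), bool)
        b[:, :4] = True  # ml = left half of hist
        r = overlap_analysis(a, b, 0.1)
        assert r.overlap_pct == pytest.approx(50.0)

    def test_empty_histology_rejected(self):
        with pytest.raises(GeometryError):
            overlap_analysis(np.zeros((5, 5), bool), np.ones((5, 5), bool), 0.1)


class TestExtractRois:
    def test_single_blob(self):
        g = np.zeros((20, 20))
        g[5:10, 5:10] = CA
        rois = extract_rois(warped_from_grid(g))
        assert len(rois) == 1 and rois[0].tissue_class == "Ca"

    def test_diagonal_connectivity(self):
        g = np.zeros((20, 20))
        g[4, 4] = g[5, 5] = CA  # touching only diagonally
        assert len(extract_rois(warped_from_grid(g), connectivity=8, min_area_mm2=0)) == 1
        assert len(extract_rois(warped_from_grid(g), connectivity=4, min_area_mm2=0)) == 2

    def test_min_area_filter(self):
        g = np.zeros((20, 20))
        g[1, 1] = NC  # 0.01 mm^2 at 0.1 mm pixels... exactly at threshold
        g[10:14, 10:14] = NC
        rois = extract_rois(warped_from_grid(g), min_area_mm2=0.05)
        assert len(rois) == 1 and rois[0].n_pixels == 16

    def test_deterministic_order(self):
        g = np.zeros((20, 20))
        g[15:18, 2:5] = FT
        g[2:5, 2:5] = FT
        g[8:11, 8:11] = CA
        rois = extract_rois(warped_from_grid(g))
        assert [r.tissue_class for r in rois] == ["FT", "FT", "Ca"]
        assert rois[0].pixel_indices[0].min() < rois[1].pixel_indices[0].min()


class TestRegionConfusion:
    def _ml_mask(self, grid, px=0.1):
        return TissueLabelMask(np.asarray(grid, np.int64), px)

    def test_fully_covered_roi(self):
        g = np.zeros((20, 20))
        g[5:10, 5:10] = CA
        rois = extract_rois(warped_from_grid(g))
        cm = region_level_confusion(rois, self._ml_mask(g))
        assert cm.values[1, 1] == 1 and cm.values.sum() == 1

    def test_majority_rule(self):
        g = np.zeros((20, 20))
        g[0:10, 0:10] = NC  # 100-px NC ROI
        ml = np.zeros((20, 20))
        ml[0:10, 0:6] = FT  # 60% FT
        ml[0:10, 6:10] = NC  # 40% NC
        rois = extract_rois(warped_from_grid(g))
        cm = region_level_confusion(rois, self._ml_mask(ml))
        assert cm.values[2, 0] == 1  # (NC, FT)

    def test_predominance_tie_prefers_ca(self):
        g = np.zeros((20, 20))
        g[0:10, 0:10] = NC
        ml = np.zeros((20, 20))
        ml[0:10, 0:5] = FT
        ml[0:10, 5:10] = CA  # 50/50 tie -> Ca by precedence
        rois = extract_rois(warped_from_grid(g))
        cm = region_level_confusion(rois, self._ml_mask(ml))
        assert cm.values[2, 1] == 1

    def test_roi_outside_eem_is_missed(self):
        g = np.zeros((40, 40))
        g[2:6, 2:6] = CA  # far corner, outside the small central EEM
        ml = np.zeros((40, 40))
        eem = circle_contour(5.0, 0.1, center=(20, 20))
        rois = extract_rois(warped_from_grid(g))
        cm = region_level_confusion(rois, self._ml_mask(ml), ml_eem=eem)
        assert cm.missed[1] == 1 and cm.values.sum() == 0

    def test_unlabeled_inside_eem_is_unclassified(self):
        g = np.zeros((40, 40))
        g[18:22, 18:22] = NC  # centre, inside EEM, no ML tissue at all
        ml = np.zeros((40, 40))
        eem = circle_contour(15.0, 0.1, center=(20, 20))
        rois = extract_rois(warped_from_grid(g))
        cm = region_level_confusion(rois, self._ml_mask(ml), ml_eem=eem)
        assert cm.unclassified[2] == 1 and cm.values.sum() == 0


class TestAreaConfusion:
    def test_identical_masks_diagonal(self):
        g = np.zeros((30, 30))
        g[5:10, 5:20] = FT
        g[15:20, 5:10] = CA
        g[22:26, 5:10] = NC
        w = warped_from_grid(g)
        cm = area_level_confusion(w, TissueLabelMask(g.astype(np.int64), 0.1))
        assert np.allclose(cm.values, np.diag(np.diag(cm.values)))
        assert cm.values[0, 0] == pytest.approx(75 * 0.01)

    def test_relabelled_nc_moves_row_mass(self):
        g = np.zeros((30, 30))
        g[5:10, 5:20] = FT
        g[22:26, 5:10] = NC
        ml = g.copy()
        ml[ml == NC] = FT
        w = warped_from_grid(g)
        cm = area_level_confusion(w, TissueLabelMask(ml.astype(np.int64), 0.1))
        assert cm.values[2, 0] > 0 and cm.values[2, 2] == 0

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        g = rng.choice([BACKGROUND, FT, CA, NC], size=(40, 40), p=[0.4, 0.4, 0.1, 0.1])
        ml = rng.choice([BACKGROUND, FT, CA, NC], size=(40, 40), p=[0.3, 0.5, 0.1, 0.1])
        eem = circle_contour(12.0, 0.1, center=(20, 20))
        w = warped_from_grid(g)
        cm = area_level_confusion(w, TissueLabelMask(ml.astype(np.int64), 0.1), eem)
        plaque_area = np.isin(g, TISSUE_CODES).sum() * 0.01
        total = cm.values.sum() + cm.missed.sum() + cm.unclassified.sum()
        assert total == pytest.approx(plaque_area)


class TestMetrics:
    def test_identity_matrix_perfect(self):
        m = metrics_from_confusion(ConfusionMatrix("region", np.diag([5, 5, 5])))
        assert m.accuracy_pct == 100.0
        assert all(
            v.sensitivity == v.precision == v.f_score == 1.0
            for v in m.per_class.values()
        )

    def test_weighted_sensitivity_equals_accuracy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.integers(0, 40, size=(3, 3)).astype(float)
            if np.any(v.sum(axis=1) == 0):
                continue
            m = metrics_from_confusion(ConfusionMatrix("area", v))
            assert m.weighted_sensitivity == pytest.approx(m.accuracy_pct / 100.0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            v = rng.integers(1, 50, size=(3, 3)).astype(float)
            m = metrics_from_confusion(ConfusionMatrix("area", v))
            for i, name in enumerate(("FT", "Ca", "NC")):
                tp = v[i, i]
                fn = v[i].sum() - tp
                fp = v[:, i].sum() - tp
                assert m.per_class[name].sensitivity == pytest.approx(tp / (tp + fn))
                assert m.per_class[name].precision == pytest.approx(tp / (tp + fp))

    def test_class_permutation_equivariance(self):
        v = np.array([[50.0, 3, 2], [4, 30, 1], [9, 2, 20]])
        perm = [2, 0, 1]
        m1 = metrics_from_confusion(ConfusionMatrix("area", v))
        m2 = metrics_from_confusion(
            ConfusionMatrix("area", v[np.ix_(perm, perm)], classes=("NC", "FT", "Ca"))
        )
        for name in ("FT", "Ca", "NC"):
            assert m1.per_class[name].f_score == pytest.approx(m2.per_class[name].f_score)
        assert m1.accuracy_pct == pytest.approx(m2.accuracy_pct)

    def test_empty_matrix_rejected(self):
        with pytest.raises(GeometryError):
            metrics_from_confusion(ConfusionMatrix("area", np.zeros((3, 3))))

    def test_region_mode_requires_integers(self):
        with pytest.raises(GeometryError):
            ConfusionMatrix("region", np.full((3, 3), 0.5))


class TestMissedTissue:
    def test_no_missed_mass(self):
        cm = ConfusionMatrix("area", np.diag([5.0, 5, 5]))
        rep = missed_tissue_report(cm)
        assert np.allclose(rep["missed_pct"], 0)

    def test_nc_example(self):
        v = np.zeros((3, 3))
        v[2, 2] = 17.9  # NC detected inside the EEM
        cm = ConfusionMatrix("area", v, missed=np.array([0, 0, 3.68]))
        rep = missed_tissue_report(cm)
        assert rep.loc[2, "missed_pct"] == pytest.approx(17.05, abs=0.1)

    def test_all_outside(self):
        v = np.zeros((3, 3))
        v[0, 0] = 1.0
        cm = ConfusionMatrix("area", v, missed=np.array([0, 4.2, 0]))
        rep = missed_tissue_report(cm)
        assert rep.loc[1, "missed_pct"] == pytest.approx(100.0)

    def test_region_mode_rejected(self):
        with pytest.raises(GeometryError):
            missed_tissue_report(ConfusionMatrix("region", np.diag([1.0, 1, 1])))


class TestErrorVsBurden:
    def test_proportional_error(self):
        burden = np.linspace(30, 80, 20)
        assert error_vs_burden(0.1 * burden, burden).r == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(9)
        r = error_vs_burden(rng.normal(size=1000), rng.uniform(30, 80, 1000)).r
        assert abs(r) < 0.1

    def test_constant_error_rejected(self):
        with pytest.raises(StatError):
            error_vs_burden(np.ones(10), np.linspace(0, 1, 10))
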