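import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from plaqueval.quant import (
    StatError,
    areas_from_mask,
    bland_altman,
    cohort_quant_table,
    concordance_correlation,
    normality_and_t,
    pearson_correlation,
    rank_sum_test,
)
from plaqueval.labels import FT

from .conftest import annulus_frame

finite_floats = st.floats(-1e6, 1e6)
vectors = st.lists(finite_floats, min_size=3, max_size=30)


class TestBlandAltman:
    def test_identity(self):
        r = bland_altman([1, 2, 3], [1, 2, 3])
        assert r.bias == 0 and r.sd == 0

    def test_hand_computed(self):
        r = bland_altman([1, 2, 3], [2, 3, 5])
        assert r.bias == pytest.approx(-1.3333, abs=1e-4)
        assert r.sd == pytest.approx(0.5774, abs=1e-4)
        assert r.loa_low == pytest.approx(r.bias - 1.96 * r.sd)

    def test_constant_shift(self):
        a = np.arange(5.0)
        r = bland_altman(a + 2, a)
        assert r.bias == pytest.approx(2.0) and r.sd == 0

    def test_needs_two_pairs(self):
        with pytest.raises(StatError):
            bland_altman([1], [2])

    @given(st.lists(st.tuples(finite_floats, finite_floats), min_size=2, max_size=20))
    def test_swap_antisymmetry(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        fwd, rev = bland_altman(a, b), bland_altman(b, a)
        assert fwd.bias == pytest.approx(-rev.bias, abs=1e-6 * (1 + abs(fwd.bias)))
        assert fwd.sd == pytest.approx(rev.sd, rel=1e-9, abs=1e-9)


class TestConcordanceCorrelation:
    def test_perfect_concordance(self):
        assert concordance_correlation([1, 2, 3], [1, 2, 3]).ccc == pytest.approx(1.0)

    def test_direct_formula(self):
        # cov = 4/3, vars 2/3 and 8/3, mean gap^2 = 4 -> 4/11
        r = concordance_correlation([1, 2, 3], [2, 4, 6])
        assert r.ccc == pytest.approx(4 / 11, abs=1e-4)
        assert r.ci_low <= r.ccc <= r.ci_high

    def test_negative_for_reversed(self):
        a = np.arange(10.0)
        assert concordance_correlation(a, -a + 5).ccc < 0

    def test_both_constant_rejected(self):
        with pytest.raises(StatError):
            concordance_correlation([1, 1, 1], [2, 2, 2])

    def test_ci_brackets_estimate_on_noisy_data(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = a + rng.normal(scale=0.5, size=50)
        r = concordance_correlation(a, b)
        assert r.ci_low < r.ccc < r.ci_high
        assert -1 <= r.ci_low and r.ci_high <= 1

    @given(vectors, vectors)
    def test_lin_inequality(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.std() == 0 or b.std() == 0:
            return
        ccc = concordance_correlation(a, b).ccc
        r = np.corrcoef(a, b)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-9


class TestRankSum:
    def test_complete_separation(self):
        assert rank_sum_test([1, 2], [3, 4]).u_statistic == 0

    def test_brute_force_small(self):
        # pairs (1>2)? no, (1>4)? no, (3>2)? yes, (3>4)? no -> U = 1
        assert rank_sum_test([1, 3], [2, 4]).u_statistic == 1

    def test_identical_multisets(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert rank_sum_test(a, a).u_statistic == pytest.approx(len(a) ** 2 / 2)

    def test_empty_rejected(self):
        with pytest.raises(StatError):
            rank_sum_test([], [1])

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=12),
        st.lists(st.integers(0, 50), min_size=1, max_size=12),
    )
    def test_u_plus_u_prime(self, a, b):
        u1 = rank_sum_test(a, b).u_statistic
        u2 = rank_sum_test(b, a).u_statistic
        assert u1 + u2 == pytest.approx(len(a) * len(b))


class TestNormalityAndT:
    def test_normal_samples_take_t_branch(self):
        rng = np.random.default_rng(42)
        res = normality_and_t(rng.normal(size=100), rng.normal(size=100))
        assert res.branch == "t-test"

    def test_heavy_tailed_takes_rank_branch(self):
        rng = np.random.default_rng(7)
        heavy = rng.standard_cauchy(size=200)
        res = normality_and_t(heavy, rng.normal(size=200))
        assert res.branch == "rank-sum"

    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        res = normality_and_t(x, x.copy())
        assert res.p_value > 0.9

    def test_small_groups_rejected(self):
        with pytest.raises(StatError):
            normality_and_t([1, 2], [1, 2, 3])


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x).r == pytest.approx(1.0)

    def test_hand_computed(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(11)
        r = pearson_correlation(rng.normal(size=1000), rng.normal(size=1000)).r
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(StatError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestAreasFromMask:
    def test_annulus_areas(self):
        geom, mask = annulus_frame(0.01)
        rec = areas_from_mask(mask, geom)
        assert rec.eem_area == pytest.approx(np.pi * 1.6**2, rel=0.01)
        assert rec.lumen_area == pytest.approx(np.pi, rel=0.01)
        assert rec.plaque_area == pytest.approx(rec.eem_area - rec.lumen_area, abs=1e-9)
        assert rec.ca_area == pytest.approx(np.pi * (1.5**2 - 1.2**2), rel=0.02)
        assert rec.plaque_burden == pytest.approx(
            100 * rec.plaque_area / rec.eem_area
        )

    def test_all_background_zero_tissue(self):
        geom, mask = annulus_frame(0.02)
        grid = mask.grid.copy()
        grid[:] = 0
        rec = areas_from_mask(type(mask)(grid, 0.02), geom)
        assert rec.ft_area == rec.ca_area == rec.nc_area == 0.0

    def test_simple_pixel_count(self):
        geom, mask = annulus_frame(0.1)
        grid = np.zeros_like(mask.grid)
        grid[:10, :10] = FT  # 100 FT px at 0.1 mm pixels -> 1.0 mm^2
        rec = areas_from_mask(
            type(mask)(grid, 0.1), geom, tissue_tolerance_mm2=1e9
        )
        assert rec.ft_area == pytest.approx(100 * 0.1**2)


class TestCohortQuantTable:
    def _records(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            eem = 10 + rng.normal()
            lumen = 4 + 0.3 * rng.normal()
            from plaqueval.quant import FrameQuantRecord

            recs.append(
                FrameQuantRecord(
                    frame_id=f"f{i}",
                    source="histology",
                    eem_area=eem,
                    lumen_area=lumen,
                    plaque_area=eem - lumen,
                    plaque_burden=100 * (eem - lumen) / eem,
                    ft_area=3 + 0.2 * rng.normal(),
                    ca_area=abs(rng.normal()) * 0.5,
                    nc_area=abs(rng.normal()) * 0.3,
                )
            )
        return recs

    def test_identical_records(self):
        hist = self._records()
        ml = [dataclasses.replace(r, source="ML") for r in hist]
        df, results = cohort_quant_table(hist, ml)
        assert np.allclose(df["mean_difference"], 0)
        assert np.allclose(df["ccc"], 1)

    def test_constant_eem_shift(self):
        hist = self._records()
        ml = [
            dataclasses.replace(
                r,
                source="ML",
                eem_area=r.eem_area + 1.0,
                plaque_area=r.plaque_area + 1.0,
                plaque_burden=100 * (r.plaque_area + 1.0) / (r.eem_area + 1.0),
            )
            for r in hist
        ]
        df, results = cohort_quant_table(hist, ml)
        assert results["eem_area"].mean_difference == pytest.approx(-1.0)
        assert results["eem_area"].ccc < 1.0

    def test_lumen_not_compared(self):
        df, _ = cohort_quant_table(self._records(), self._records())
        assert not any("umen" in q for q in df["quantity"])

    def test_unpaired_ids_rejected(self):
        hist = self._records(5)
        ml = self._records(4)
        with pytest.raises(StatError, match="f4"):
            cohort_quant_table(hist, ml)
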