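"""Quantitative agreement between histology and classifier estimations.

Per-frame plaque measurements (EEM area, plaque area = EEM − lumen,
plaque burden, and per-class tissue areas) are compared across the two
sources with the battery conventional for method-agreement studies:
Mann–Whitney U for the paired distributions, Bland–Altman bias and 95%
limits of agreement, Lin's concordance correlation coefficient with a
Fisher-z asymptotic confidence interval, Kolmogorov–Smirnov normality
screening with Student's t as the parametric branch, and Pearson
correlation for error-versus-burden relations.

Differences are reported as histology − classifier throughout, so a
negative bias means the classifier overestimates. Lumen areas are
computed but deliberately never compared: decompressed histology lumens
are not commensurable with pressurized in vivo lumens.

Lin's CCC uses population (1/n) moments, the conventional definition;
Bland–Altman uses the sample (1/(n−1)) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    FrameGeometry,
    GeometryError,
    TissueLabelMask,
    plaque_area,
    plaque_burden,
)
from .labels import CA, FT, NC

__all__ = [
    "StatError",
    "FrameQuantRecord",
    "PairedStatResult",
    "areas_from_mask",
    "bland_altman",
    "concordance_correlation",
    "rank_sum_test",
    "normality_and_t",
    "pearson_correlation",
    "cohort_quant_table",
    "QUANT_QUANTITIES",
]

ALPHA = 0.05  # significance threshold used throughout


class StatError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass
class FrameQuantRecord:
    """Table-row quantities for one frame from one source."""

    frame_id: str
    source: str  # "histology" | "ML"
    eem_area: float
    lumen_area: float
    plaque_area: float
    plaque_burden: float
    ft_area: float
    ca_area: float
    nc_area: float

    def __post_init__(self) -> None:
        if abs(self.plaque_area - (self.eem_area - self.lumen_area)) > 1e-6:
            raise StatError(
                f"frame {self.frame_id!r}: plaque_area != eem_area - lumen_area"
            )


def areas_from_mask(
    mask: TissueLabelMask,
    geometry: FrameGeometry,
    source: str = "histology",
    tissue_tolerance_mm2: Optional[float] = None,
) -> FrameQuantRecord:
    """Per-frame areas: EEM/lumen from contours, tissue classes from the mask.

    The mask-counted tissue total may exceed the polygon plaque area by a
    rasterisation margin of order perimeter x pixel size; anything beyond
    that margin indicates inconsistent annotations and is rejected.
    """
    if mask.pixel_size_mm != geometry.pixel_size_mm:
        raise GeometryError("mask and geometry pixel sizes differ")
    eem = geometry.eem_area_mm2()
    lumen = geometry.lumen_area_mm2()
    plaque = plaque_area(eem, lumen)
    ft = mask.class_area_mm2(FT)
    ca = mask.class_area_mm2(CA)
    nc = mask.class_area_mm2(NC)
    if tissue_tolerance_mm2 is None:
        tissue_tolerance_mm2 = (
            geometry.lumen.perimeter_mm + geometry.eem.perimeter_mm
        ) * mask.pixel_size_mm + 1e-6
    if ft + ca + nc > plaque + tissue_tolerance_mm2:
        raise StatError(
            f"frame {geometry.frame_id!r}: tissue areas {ft + ca + nc:.3f} mm^2 "
            f"exceed plaque area {plaque:.3f} mm^2 beyond rasterisation tolerance"
        )
    return FrameQuantRecord(
        frame_id=geometry.frame_id,
        source=source,
        eem_area=eem,
        lumen_area=lumen,
        plaque_area=plaque,
        plaque_burden=plaque_burden(plaque, eem),
        ft_area=ft,
        ca_area=ca,
        nc_area=nc,
    )


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltman:
    """Bias = mean(a − b), sample SD of the differences, bias ± 1.96·SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatError("inputs must be paired 1-D vectors of equal length")
    if len(a) < 2:
        raise StatError("Bland-Altman needs at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, len(a))


@dataclass
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def concordance_correlation(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA
) -> CCCResult:
    """Lin's concordance correlation coefficient with Fisher-z CI.

    ccc = 2·cov(a,b) / (var(a) + var(b) + (mean(a) − mean(b))^2) with
    population (1/n) moments. The confidence interval and p-value use the
    asymptotic variance of the z-transformed coefficient.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise StatError("CCC needs paired vectors with n >= 3")
    n = len(a)
    va = float(a.var())
    vb = float(b.var())
    if va == 0.0 and vb == 0.0:
        raise StatError("CCC undefined: both vectors are constant")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    gap2 = (a.mean() - b.mean()) ** 2
    ccc = 2.0 * cov / (va + vb + gap2)
    if va == 0.0 or vb == 0.0:
        # degenerate: one constant vector -> ccc is 0, no meaningful CI
        return CCCResult(float(ccc), float(ccc), float(ccc), 1.0, n)
    r = cov / np.sqrt(va * vb)
    if abs(ccc) >= 1.0 - 1e-12 or abs(r) < 1e-12:
        return CCCResult(float(ccc), float(ccc), float(ccc), 0.0 if ccc else 1.0, n)
    u2 = gap2 / np.sqrt(va * vb)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        se2 = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
            + 4 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
            - 2 * ccc**4 * u2**2 / (r**2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
    if not np.isfinite(se2):
        return CCCResult(float(ccc), float(ccc), float(ccc), 1.0, n)
    se = np.sqrt(max(se2, 0.0))
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    p = 2 * stats.norm.sf(abs(z) / se) if se > 0 else 0.0
    return CCCResult(float(ccc), float(lo), float(hi), float(p), n)


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Mann–Whitney U: count of (a_i > b_j) pairs plus half ties.

    Exact enumeration when both samples are small (min n <= 8, no ties),
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise StatError("rank-sum test needs non-empty samples")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if min(len(a), len(b)) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


@dataclass
class NormalityComparison:
    ks_p_a: float
    ks_p_b: float
    branch: str  # "t-test" | "rank-sum"
    p_value: float


def normality_and_t(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA
) -> NormalityComparison:
    """KS-vs-fitted-normal screening, then Student's t or the rank test.

    Each group is tested against a normal distribution with its own fitted
    mean and SD; the parametric branch runs only if both groups pass at
    ``alpha``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise StatError("normality screening needs n >= 3 per group")

    def ks_p(x: np.ndarray) -> float:
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0  # a constant sample is not normal
        return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

    pa, pb = ks_p(a), ks_p(b)
    if pa > alpha and pb > alpha:
        p = float(stats.ttest_ind(a, b).pvalue)
        return NormalityComparison(pa, pb, "t-test", p)
    p = rank_sum_test(a, b).p_value
    return NormalityComparison(pa, pb, "rank-sum", p)


@dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatError("Pearson correlation needs paired vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), len(x))


@dataclass
class PairedStatResult:
    """One agreement-table row for one quantity."""

    quantity: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    p_rank_test: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    ccc_p: float

    def __post_init__(self) -> None:
        if not (self.loa_low - 1e-9 <= self.mean_difference <= self.loa_high + 1e-9):
            raise StatError("limits of agreement must bracket the mean difference")


#: quantities compared between histology and classifier output, in table
#: order; lumen area is intentionally absent.
QUANT_QUANTITIES: dict[str, str] = {
    "eem_area": "EEM area, mm^2",
    "plaque_area": "Plaque area, mm^2",
    "plaque_burden": "Plaque burden, %",
    "ft_area": "FT area, mm^2",
    "ca_area": "Ca area, mm^2",
    "nc_area": "NC area, mm^2",
}


def cohort_quant_table(
    hist_records: Sequence[FrameQuantRecord],
    ml_records: Sequence[FrameQuantRecord],
) -> tuple[pd.DataFrame, dict[str, PairedStatResult]]:
    """Per-quantity agreement table over a cohort of matched frames.

    Records are paired by ``frame_id``; unpaired ids are an error. Returns
    the table as a DataFrame (one row per quantity, columns mirroring the
    conventional mean ± SD / mean difference / rank-test p / CCC layout)
    plus the structured per-quantity results.
    """
    hist_by_id = {r.frame_id: r for r in hist_records}
    ml_by_id = {r.frame_id: r for r in ml_records}
    unpaired = sorted(set(hist_by_id) ^ set(ml_by_id))
    if unpaired:
        raise StatError(f"unpaired frame ids: {unpaired}")
    ids = sorted(hist_by_id)
    results: dict[str, PairedStatResult] = {}
    rows = []
    for attr, label in QUANT_QUANTITIES.items():
        a = np.array([getattr(hist_by_id[i], attr) for i in ids], float)
        b = np.array([getattr(ml_by_id[i], attr) for i in ids], float)
        ba = bland_altman(a, b)
        if len(a) < 3:
            ccc = CCCResult(np.nan, np.nan, np.nan, np.nan, len(a))
        else:
            try:
                ccc = concordance_correlation(a, b)
            except StatError:
                # both vectors constant: perfect agreement iff identical
                val = 1.0 if np.allclose(a, b) else 0.0
                ccc = CCCResult(val, val, val, np.nan, len(a))
        if np.array_equal(a, b):
            p_rank = 1.0
        else:
            p_rank = rank_sum_test(a, b).p_value
        res = PairedStatResult(
            quantity=label,
            n=len(ids),
            mean_a=float(a.mean()),
            sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            mean_b=float(b.mean()),
            sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
            mean_difference=ba.bias,
            sd_difference=ba.sd,
            loa_low=ba.loa_low,
            loa_high=ba.loa_high,
            p_rank_test=p_rank,
            ccc=ccc.ccc,
            ccc_ci_low=ccc.ci_low,
            ccc_ci_high=ccc.ci_high,
            ccc_p=ccc.p_value,
        )
        results[attr] = res
        rows.append(
            {
                "quantity": label,
                "n": res.n,
                "histology_mean": res.mean_a,
                "histology_sd": res.sd_a,
                "ml_mean": res.mean_b,
                "ml_sd": res.sd_b,
                "mean_difference": res.mean_difference,
                "sd_difference": res.sd_difference,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "p_rank_test": res.p_rank_test,
                "ccc": res.ccc,
                "ccc_ci_low": res.ccc_ci_low,
                "ccc_ci_high": res.ccc_ci_high,
                "ccc_p": res.ccc_p,
            }
        )
    return pd.DataFrame(rows), results
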