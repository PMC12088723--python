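"""Qualitative agreement: overlap, ROIs, confusion matrices and metrics.

Histology is the reference standard. Connected regions of one tissue
class in the warped histology mask define regions of interest (ROIs);
region-level analysis assigns each ROI the classifier's predominant
tissue type, area-level analysis cross-tabulates per-pixel areas in mm^2.
Histology tissue falling outside the classifier's EEM border cannot be
seen by the classifier at all and is tallied separately as "missed"
rather than entering the 3x3 matrix; classifier-unlabeled plaque inside
the EEM is likewise surfaced as "unclassified" instead of being silently
folded into a class.

Per-class metrics follow the usual multi-class one-vs-rest definitions:
sensitivity = TP/(TP+FN) (diagonal over row sum), precision = TP/(TP+FP)
(diagonal over column sum), F-score their harmonic mean; accuracy is
100 x trace/total. Overall sensitivity/precision/F are weighted averages
with the row sums (class prevalences) as weights, which makes overall
weighted sensitivity identical to accuracy/100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .coregister import WarpedHistology
from .geometry import Contour, GeometryError, TissueLabelMask, contains_points
from .labels import CA, FT, NC, PREDOMINANCE_PRIORITY, TISSUE_CLASSES, TISSUE_CODES
from .quant import PearsonResult, StatError, pearson_correlation

__all__ = [
    "OverlapResult",
    "ROI",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "overlap_analysis",
    "extract_rois",
    "region_level_confusion",
    "area_level_confusion",
    "metrics_from_confusion",
    "missed_tissue_report",
    "error_vs_burden",
]

_CODE_TO_ROW = {code: i for i, code in enumerate(TISSUE_CODES)}


@dataclass
class OverlapResult:
    """Plaque-footprint overlap between the two estimations, in percent."""

    overlap_pct: float  # |hist ∩ ml| / |hist| x 100
    hist_only_pct: float  # |hist \ ml| / |hist| x 100
    ml_only_pct: float  # |ml \ hist| / |ml| x 100 (0 if ml empty)
    hist_area_mm2: float
    ml_area_mm2: float


def overlap_analysis(
    warped_plaque: np.ndarray, ml_plaque: np.ndarray, pixel_size_mm: float
) -> OverlapResult:
    """Overlapping / non-overlapping plaque area analysis on one grid."""
    h = np.asarray(warped_plaque, bool)
    m = np.asarray(ml_plaque, bool)
    if h.shape != m.shape:
        raise GeometryError("plaque masks must share the grid")
    n_h = int(h.sum())
    n_m = int(m.sum())
    if n_h == 0:
        raise GeometryError("histology plaque is empty: overlap undefined")
    inter = int((h & m).sum())
    px2 = pixel_size_mm**2
    return OverlapResult(
        overlap_pct=100.0 * inter / n_h,
        hist_only_pct=100.0 * (n_h - inter) / n_h,
        ml_only_pct=100.0 * (n_m - inter) / n_m if n_m else 0.0,
        hist_area_mm2=n_h * px2,
        ml_area_mm2=n_m * px2,
    )


@dataclass
class ROI:
    """One connected histology-defined region of a single tissue class."""

    tissue_class: str
    pixel_indices: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area_mm2: float
    frame_id: str = ""

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_indices[0])


def extract_rois(
    warped: WarpedHistology,
    connectivity: int = 8,
    min_area_mm2: float = 0.01,
    frame_id: str = "",
) -> list[ROI]:
    """Connected-component ROIs per tissue class from warped histology.

    ``connectivity`` is 4 or 8 (8 by default: diagonally touching pixels
    join). Components below ``min_area_mm2`` are dropped as warp speckle.
    Ordering is deterministic: class order FT, Ca, NC, then top-left pixel.
    """
    if connectivity not in (4, 8):
        raise GeometryError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    px2 = warped.mask.pixel_size_mm**2
    rois: list[ROI] = []
    valid = warped.valid_region
    for cls_name, code in zip(TISSUE_CLASSES, TISSUE_CODES):
        cls_mask = valid & (warped.mask.grid == code)
        labeled = measure.label(cls_mask, connectivity=skimage_conn)
        comps = []
        for lab in range(1, labeled.max() + 1):
            idx = np.nonzero(labeled == lab)
            area = len(idx[0]) * px2
            if area < min_area_mm2:
                continue
            comps.append((idx[0].min(), idx[1].min(), idx, area))
        comps.sort(key=lambda c: (c[0], c[1]))
        for _, _, idx, area in comps:
            rois.append(ROI(cls_name, idx, area, frame_id))
    return rois


@dataclass
class ConfusionMatrix:
    """3x3 histology-vs-classifier tallies with side columns.

    ``mode`` is "region" (integer ROI counts) or "area" (mm^2). Rows are
    histology classes, columns classifier classes, both in FT/Ca/NC order.
    ``missed`` holds per-histology-class mass outside the classifier EEM;
    ``unclassified`` holds plaque inside the EEM the classifier left
    unlabeled. Neither enters the 3x3 metrics.
    """

    mode: str
    values: np.ndarray
    missed: np.ndarray = field(default_factory=lambda: np.zeros(3))
    unclassified: np.ndarray = field(default_factory=lambda: np.zeros(3))
    classes: tuple[str, ...] = TISSUE_CLASSES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.missed = np.asarray(self.missed, float)
        self.unclassified = np.asarray(self.unclassified, float)
        k = len(self.classes)
        if self.values.shape != (k, k):
            raise GeometryError("confusion matrix must be square over the classes")
        if np.any(self.values < 0) or np.any(self.missed < 0):
            raise GeometryError("confusion entries must be non-negative")
        if self.mode == "region" and not np.allclose(self.values, np.rint(self.values)):
            raise GeometryError("region-mode entries must be integer counts")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.mode != other.mode or self.classes != other.classes:
            raise GeometryError("cannot pool confusion matrices of different kinds")
        return ConfusionMatrix(
            self.mode,
            self.values + other.values,
            self.missed + other.missed,
            self.unclassified + other.unclassified,
            self.classes,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.classes), columns=list(self.classes))
        df["missed_outside_eem"] = self.missed
        df["unclassified"] = self.unclassified
        return df


def _predominant_class(counts: dict[int, float]) -> int:
    """Largest-share class; ties broken by the Ca > NC > FT precedence."""
    best = max(counts.values())
    for code in PREDOMINANCE_PRIORITY:
        if counts.get(code, 0.0) == best:
            return code
    raise RuntimeError("unreachable")


def region_level_confusion(
    rois: Sequence[ROI],
    ml_mask: TissueLabelMask,
    ml_eem: Optional[Contour] = None,
) -> ConfusionMatrix:
    """Predominant-tissue tally: one count per ROI.

    Each ROI contributes to cell (its histology class, the classifier's
    predominant class among classifier tissue pixels inside it). An ROI
    containing no classifier tissue is "missed" when it lies (mostly)
    outside the classifier EEM, otherwise "unclassified".
    """
    values = np.zeros((3, 3))
    missed = np.zeros(3)
    unclassified = np.zeros(3)
    inside_eem_grid = None
    if ml_eem is not None:
        h, w = ml_mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
        inside_eem_grid = contains_points(ml_eem, pts).reshape(h, w)
    for roi in rois:
        row = _CODE_TO_ROW[dict(zip(TISSUE_CLASSES, TISSUE_CODES))[roi.tissue_class]]
        ml_vals = ml_mask.grid[roi.pixel_indices]
        counts = {code: float(np.count_nonzero(ml_vals == code)) for code in TISSUE_CODES}
        if sum(counts.values()) > 0:
            values[row, _CODE_TO_ROW[_predominant_class(counts)]] += 1
        else:
            if inside_eem_grid is not None:
                outside_frac = float(np.mean(~inside_eem_grid[roi.pixel_indices]))
            else:
                outside_frac = 0.0
            if outside_frac > 0.5:
                missed[row] += 1
            else:
                unclassified[row] += 1
    return ConfusionMatrix("region", values, missed, unclassified)


def area_level_confusion(
    warped: WarpedHistology,
    ml_mask: TissueLabelMask,
    ml_eem: Optional[Contour] = None,
) -> ConfusionMatrix:
    """Per-pixel area cross-tabulation in mm^2.

    Cell (h, m) is the area labeled h by warped histology and m by the
    classifier. Histology tissue outside the classifier EEM goes to the
    missed column; inside-EEM pixels the classifier left without a tissue
    label go to the unclassified column. Total tallied mass therefore
    equals the warped histology plaque area (conservation).
    """
    if warped.mask.shape != ml_mask.shape:
        raise GeometryError("warped and classifier masks must share the grid")
    px2 = warped.mask.pixel_size_mm**2
    hist_grid = warped.mask.grid
    tissue = warped.plaque_mask()
    if ml_eem is not None:
        h, w = ml_mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
        inside_eem = contains_points(ml_eem, pts).reshape(h, w)
    else:
        inside_eem = np.ones(ml_mask.shape, bool)
    values = np.zeros((3, 3))
    missed = np.zeros(3)
    unclassified = np.zeros(3)
    for hi, hcode in enumerate(TISSUE_CODES):
        sel = tissue & (hist_grid == hcode)
        missed[hi] = np.count_nonzero(sel & ~inside_eem) * px2
        sel_in = sel & inside_eem
        ml_vals = ml_mask.grid[sel_in]
        for mi, mcode in enumerate(TISSUE_CODES):
            values[hi, mi] = np.count_nonzero(ml_vals == mcode) * px2
        unclassified[hi] = (
            np.count_nonzero(sel_in) - np.count_nonzero(np.isin(ml_vals, TISSUE_CODES))
        ) * px2
    return ConfusionMatrix("area", values, missed, unclassified)


@dataclass
class ClassMetrics:
    sensitivity: float
    precision: float
    f_score: float


@dataclass
class ClassificationMetrics:
    per_class: dict[str, ClassMetrics]
    weighted_sensitivity: float
    weighted_precision: float
    weighted_f_score: float
    accuracy_pct: float
    missed: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": name,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
                "f_score": m.f_score,
            }
            for name, m in self.per_class.items()
        ]
        rows.append(
            {
                "class": "overall (weighted)",
                "sensitivity": self.weighted_sensitivity,
                "precision": self.weighted_precision,
                "f_score": self.weighted_f_score,
            }
        )
        df = pd.DataFrame(rows)
        df["accuracy_pct"] = [np.nan] * (len(rows) - 1) + [self.accuracy_pct]
        return df


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Per-class and prevalence-weighted overall metrics from a 3x3 matrix.

    Sensitivity = diagonal/row sum, precision = diagonal/column sum,
    F = 2ps/(p+s); accuracy = 100 x trace/total. Overall values weight the
    per-class metrics by row sums. The missed/unclassified columns do not
    enter; they are carried through for separate reporting.
    """
    v = cm.values
    total = v.sum()
    if total <= 0:
        raise GeometryError("empty confusion matrix")
    row = v.sum(axis=1)
    col = v.sum(axis=0)
    diag = np.diag(v)
    per_class: dict[str, ClassMetrics] = {}
    sens = np.zeros(len(cm.classes))
    prec = np.zeros(len(cm.classes))
    f = np.zeros(len(cm.classes))
    for i, name in enumerate(cm.classes):
        s = diag[i] / row[i] if row[i] > 0 else 0.0
        p = diag[i] / col[i] if col[i] > 0 else 0.0
        fi = 2 * p * s / (p + s) if (p + s) > 0 else 0.0
        sens[i], prec[i], f[i] = s, p, fi
        per_class[name] = ClassMetrics(float(s), float(p), float(fi))
    w = row / total
    return ClassificationMetrics(
        per_class=per_class,
        weighted_sensitivity=float(np.dot(w, sens)),
        weighted_precision=float(np.dot(w, prec)),
        weighted_f_score=float(np.dot(w, f)),
        accuracy_pct=float(100.0 * diag.sum() / total),
        missed=cm.missed.copy(),
    )


def missed_tissue_report(area_cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class tissue mass outside the classifier EEM border.

    The percentage is missed / (in-EEM row total + missed) x 100, i.e. the
    share of each histology class the classifier could not even see.
    """
    if area_cm.mode != "area":
        raise GeometryError("missed-tissue report needs an area-mode matrix")
    rows = []
    for i, name in enumerate(area_cm.classes):
        inside = area_cm.values[i].sum() + area_cm.unclassified[i]
        missed = area_cm.missed[i]
        denom = inside + missed
        rows.append(
            {
                "class": name,
                "missed_mm2": missed,
                "missed_pct": 100.0 * missed / denom if denom > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def error_vs_burden(
    plaque_area_errors: Sequence[float], burdens: Sequence[float]
) -> PearsonResult:
    """Correlation of per-frame plaque-area error (hist − ML) with burden."""
    return pearson_correlation(burdens, plaque_area_errors)
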