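"""Readers/writers for masks, contours, landmarks and manifests; pipeline.

On-disk conventions: masks are single-channel indexed PNG (TIFF accepted
for high-resolution histology) whose pixel values are label codes, with a
JSON sidecar mapping class names to codes and recording the pixel size;
contours, landmarks and manifests are JSON; configs are YAML. All
coordinates are 0-based, row-major, y-down. Classifier "lipid" labels are
remapped to necrotic core on load.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import agreement, quant
from .coregister import (
    HistologyFrame,
    ImagingFrame,
    LandmarkCorrespondence,
    MatchedPair,
    WarpedHistology,
    render_hybrid,
    warp_histology,
)
from .geometry import Contour, FrameGeometry, GeometryError, TissueLabelMask
from .labels import DEFAULT_CODES, MACROPHAGE, NC, code_for_class
from .macrophage import CD68Mask, compare_macrophage, detect_macrophage_rich
from .synthetic import SyntheticConfig, SyntheticPair

log = logging.getLogger("plaqueval")

__all__ = [
    "save_mask",
    "load_mask",
    "save_contours",
    "load_contours",
    "save_landmarks",
    "load_landmarks",
    "write_pair",
    "load_matched_pair",
    "load_manifest",
    "write_cohort",
    "filter_matched_frames",
    "PipelineSettings",
    "run_pipeline",
    "load_synthetic_config",
]

MIN_FRAME_SPACING_MM = 0.4  # analysed frames must be at least this far apart


# --------------------------------------------------------------------------
# masks


def save_mask(path, mask: TissueLabelMask) -> None:
    path = Path(path)
    grid = np.asarray(mask.grid)
    if grid.max(initial=0) > 255 or grid.min(initial=0) < 0:
        raise GeometryError("label codes must fit in uint8 for indexed output")
    Image.fromarray(grid.astype(np.uint8), mode="L").save(path)
    sidecar = {
        "pixel_size_mm": mask.pixel_size_mm,
        "labels": {name: int(code) for name, code in mask.codes.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_mask(path) -> TissueLabelMask:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing label sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    grid = np.asarray(Image.open(path)).astype(np.int64)
    if grid.ndim != 2:
        raise GeometryError(f"{path}: mask must be single-channel")
    codes = dict(DEFAULT_CODES)
    remap = {}
    for name, code in sidecar["labels"].items():
        canonical = code_for_class(name)
        if code != canonical:
            remap[int(code)] = canonical
    if remap:
        out = grid.copy()
        for src, dst in remap.items():
            out[grid == src] = dst
        grid = out
    present = set(np.unique(grid).tolist())
    unknown = present - set(codes.values())
    if unknown:
        raise GeometryError(f"{path}: unknown label codes {sorted(unknown)}")
    return TissueLabelMask(grid, float(sidecar["pixel_size_mm"]), codes=codes)


# --------------------------------------------------------------------------
# contours / frames / landmarks


def save_contours(path, geometry: FrameGeometry) -> None:
    payload = {
        "frame_id": geometry.frame_id,
        "longitudinal_position_mm": geometry.longitudinal_position_mm,
        "pixel_size_mm": geometry.pixel_size_mm,
        "lumen": np.asarray(geometry.lumen.points).tolist(),
        "eem": np.asarray(geometry.eem.points).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path) -> FrameGeometry:
    payload = json.loads(Path(path).read_text())
    px = float(payload["pixel_size_mm"])
    return FrameGeometry(
        lumen=Contour(payload["lumen"], px),
        eem=Contour(payload["eem"], px),
        frame_id=payload.get("frame_id", ""),
        longitudinal_position_mm=float(payload.get("longitudinal_position_mm", 0.0)),
    )


def save_landmarks(path, landmarks: LandmarkCorrespondence) -> None:
    Path(path).write_text(
        json.dumps({"pairs": np.asarray(landmarks.pairs).tolist()})
    )


def load_landmarks(path) -> LandmarkCorrespondence:
    payload = json.loads(Path(path).read_text())
    return LandmarkCorrespondence(np.asarray(payload["pairs"], float))


# --------------------------------------------------------------------------
# matched pairs and manifests


def write_pair(directory, pair: MatchedPair) -> dict:
    """Write one matched pair's files; returns its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fid = pair.frame_id or "frame"
    entry = {
        "frame_id": fid,
        "position_mm": pair.imaging.geometry.longitudinal_position_mm,
        "modality": pair.imaging.modality,
        "histology_mask": f"{fid}_hist.png",
        "histology_contours": f"{fid}_hist_contours.json",
        "imaging_mask": f"{fid}_ml.png",
        "imaging_contours": f"{fid}_ml_contours.json",
        "landmarks": f"{fid}_landmarks.json",
    }
    save_mask(directory / entry["histology_mask"], pair.histology.mask)
    save_contours(directory / entry["histology_contours"], pair.histology.geometry)
    save_mask(directory / entry["imaging_mask"], pair.imaging.mask)
    save_contours(directory / entry["imaging_contours"], pair.imaging.geometry)
    save_landmarks(directory / entry["landmarks"], pair.landmarks)
    if pair.histology.cd68 is not None:
        entry["cd68_mask"] = f"{fid}_cd68.png"
        cd68_mask = TissueLabelMask(
            pair.histology.cd68.astype(np.int64), pair.histology.mask.pixel_size_mm,
            codes={"background": 0, "lumen": 1},
        )
        save_mask(directory / entry["cd68_mask"], cd68_mask)
    return entry


def load_matched_pair(entry: dict, base_dir) -> MatchedPair:
    """Load and validate one manifest entry into a MatchedPair."""
    base = Path(base_dir)
    fid = entry.get("frame_id", "?")
    for key in ("histology_mask", "imaging_mask", "landmarks"):
        if not (base / entry[key]).exists():
            raise FileNotFoundError(f"frame {fid}: missing file {entry[key]}")
    hist_mask = load_mask(base / entry["histology_mask"])
    hist_geom = load_contours(base / entry["histology_contours"])
    ml_mask = load_mask(base / entry["imaging_mask"])
    ml_geom = load_contours(base / entry["imaging_contours"])
    landmarks = load_landmarks(base / entry["landmarks"])
    hist_geom.longitudinal_position_mm = float(entry.get("position_mm", 0.0))
    ml_geom.longitudinal_position_mm = float(entry.get("position_mm", 0.0))
    cd68 = None
    if "cd68_mask" in entry:
        cd68 = np.asarray(load_mask(base / entry["cd68_mask"]).grid, bool)
    return MatchedPair(
        histology=HistologyFrame(hist_geom, hist_mask, cd68=cd68),
        imaging=ImagingFrame(ml_geom, ml_mask, modality=entry.get("modality", "NIRS-IVUS")),
        landmarks=landmarks,
        frame_id=fid,
    )


def write_cohort(directory, cohort: Sequence[SyntheticPair], dataset: str = "synthetic") -> Path:
    """Write a synthetic cohort plus manifest and truth records."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = [write_pair(directory, sp.pair) for sp in cohort]
    manifest = {"dataset": dataset, "pairs": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    truth = []
    for sp in cohort:
        rec = dataclasses.asdict(sp.truth.record)
        rec["misclassification"] = np.asarray(rec["misclassification"]).tolist()
        rec["landmark_pairs"] = np.asarray(rec["landmark_pairs"]).tolist()
        truth.append(rec)
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))
    return directory / "manifest.json"


def load_manifest(path) -> dict:
    manifest = json.loads(Path(path).read_text())
    ids = [e["frame_id"] for e in manifest["pairs"]]
    if len(ids) != len(set(ids)):
        raise GeometryError("manifest contains duplicate frame ids")
    return manifest


def filter_matched_frames(
    entries: Sequence[dict], min_spacing_mm: float = MIN_FRAME_SPACING_MM
) -> tuple[list[dict], list[dict]]:
    """Greedy longitudinal spacing filter, scanning from the most proximal.

    A frame is kept iff its pullback position is at least ``min_spacing_mm``
    from the last kept frame. Returns (kept, excluded).
    """
    ordered = sorted(entries, key=lambda e: float(e.get("position_mm", 0.0)))
    kept: list[dict] = []
    excluded: list[dict] = []
    last = None
    for e in ordered:
        pos = float(e.get("position_mm", 0.0))
        if last is None or pos - last >= min_spacing_mm:
            kept.append(e)
            last = pos
        else:
            excluded.append(e)
    return kept, excluded


# --------------------------------------------------------------------------
# pipeline


@dataclasses.dataclass
class PipelineSettings:
    strip_depth_mm: Optional[float] = None
    connectivity: int = 8
    min_roi_area_mm2: float = 0.01
    min_spacing_mm: float = MIN_FRAME_SPACING_MM
    write_overlays: bool = False
    macrophage_window_radius_mm: float = 0.1
    macrophage_threshold: float = 0.40


def _analyse_pair(pair: MatchedPair, settings: PipelineSettings):
    warped = warp_histology(pair, strip_depth_mm=settings.strip_depth_mm)
    hist_rec = quant.areas_from_mask(
        pair.histology.mask, pair.histology.geometry, source="histology"
    )
    ml_rec = quant.areas_from_mask(pair.imaging.mask, pair.imaging.geometry, source="ML")
    overlap = agreement.overlap_analysis(
        warped.plaque_mask(), pair.imaging.mask.plaque_mask(), warped.mask.pixel_size_mm
    )
    rois = agreement.extract_rois(
        warped,
        connectivity=settings.connectivity,
        min_area_mm2=settings.min_roi_area_mm2,
        frame_id=pair.frame_id,
    )
    region_cm = agreement.region_level_confusion(
        rois, pair.imaging.mask, pair.imaging.geometry.eem
    )
    area_cm = agreement.area_level_confusion(
        warped, pair.imaging.mask, pair.imaging.geometry.eem
    )
    macro = None
    if pair.histology.cd68 is not None:
        plaque = pair.histology.mask.plaque_mask()
        cd68 = CD68Mask(
            pair.histology.cd68 & plaque, plaque, pair.histology.mask.pixel_size_mm
        )
        hist_rich = detect_macrophage_rich(
            cd68,
            window_radius_mm=settings.macrophage_window_radius_mm,
            threshold=settings.macrophage_threshold,
        )
        ml_area = pair.imaging.mask.class_area_mm2(MACROPHAGE)
        macro = (hist_rich.area_mm2, ml_area)
    return warped, hist_rec, ml_rec, overlap, region_cm, area_cm, macro


def run_pipeline(
    manifest_path,
    out_dir,
    settings: Optional[PipelineSettings] = None,
) -> dict:
    """Filter, warp and analyse a manifest of matched pairs end to end.

    Writes quant_table.csv, confusion_region.csv, confusion_area.csv,
    metrics.csv, overlap.csv, missed.csv and report.json under ``out_dir``.
    Per-frame failures are logged and skipped; the returned report lists
    them and the exit status of the CLI reflects any failure.
    """
    settings = settings or PipelineSettings()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    kept, excluded = filter_matched_frames(manifest["pairs"], settings.min_spacing_mm)
    for e in excluded:
        log.info("frame %s excluded by %.1f mm spacing filter", e["frame_id"], settings.min_spacing_mm)
    if not kept:
        raise GeometryError("no frames left after the spacing filter")

    hist_recs, ml_recs = [], []
    overlaps, failures = [], []
    region_total = area_total = None
    macro_hist, macro_ml = [], []
    for entry in kept:
        fid = entry["frame_id"]
        try:
            pair = load_matched_pair(entry, base)
            warped, hist_rec, ml_rec, overlap, region_cm, area_cm, macro = _analyse_pair(
                pair, settings
            )
        except Exception as exc:  # per-frame failures must not kill the run
            log.error("frame %s failed: %s", fid, exc)
            failures.append({"frame_id": fid, "error": str(exc)})
            continue
        hist_recs.append(hist_rec)
        ml_recs.append(ml_rec)
        overlaps.append(
            {
                "frame_id": fid,
                "overlap_pct": overlap.overlap_pct,
                "hist_only_pct": overlap.hist_only_pct,
                "ml_only_pct": overlap.ml_only_pct,
            }
        )
        region_total = region_cm if region_total is None else region_total + region_cm
        area_total = area_cm if area_total is None else area_total + area_cm
        if macro is not None:
            macro_hist.append(macro[0])
            macro_ml.append(macro[1])
        if settings.write_overlays:
            overlay = render_hybrid(pair, warped)
            Image.fromarray(overlay).save(out / f"{fid}_hybrid.png")
        log.info("frame %s analysed", fid)

    if not hist_recs:
        raise GeometryError("all frames failed; nothing to report")

    if len(hist_recs) >= 2:
        quant_df, _ = quant.cohort_quant_table(hist_recs, ml_recs)
        quant_df.to_csv(out / "quant_table.csv", index=False)
    else:
        log.warning("single analysable frame: cohort agreement table skipped")
    region_total.to_frame().to_csv(out / "confusion_region.csv")
    area_total.to_frame().to_csv(out / "confusion_area.csv")
    metrics_rows = []
    for mode, cm in (("region", region_total), ("area", area_total)):
        m = agreement.metrics_from_confusion(cm)
        df = m.to_frame()
        df.insert(0, "mode", mode)
        metrics_rows.append(df)
    pd.concat(metrics_rows).to_csv(out / "metrics.csv", index=False)
    overlap_df = pd.DataFrame(overlaps)
    overlap_df.to_csv(out / "overlap.csv", index=False)
    agreement.missed_tissue_report(area_total).to_csv(out / "missed.csv", index=False)

    report = {
        "n_frames_in_manifest": len(manifest["pairs"]),
        "n_excluded_by_spacing": len(excluded),
        "n_analysed": len(hist_recs),
        "failures": failures,
        "mean_overlap_pct": float(overlap_df["overlap_pct"].mean()),
        "region_accuracy_pct": agreement.metrics_from_confusion(region_total).accuracy_pct,
        "area_accuracy_pct": agreement.metrics_from_confusion(area_total).accuracy_pct,
    }
    if macro_hist:
        comp = compare_macrophage(macro_hist, macro_ml)
        report["macrophage"] = {
            "total_hist_mm2": comp.total_hist_mm2,
            "total_ml_mm2": comp.total_ml_mm2,
            "ccc": comp.ccc.ccc,
            "n_ml_missed": comp.n_ml_missed,
        }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def load_synthetic_config(path) -> SyntheticConfig:
    """Build a SyntheticConfig from a YAML mapping of field names."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise GeometryError(f"unknown config keys: {sorted(unknown)}")
    for key in ("misclassification",):
        if key in payload:
            payload[key] = np.asarray(payload[key], float)
    tuple_keys = {
        "lumen_harmonic_orders",
        "lumen_harmonic_amplitudes",
        "eem_thickness_range_mm",
        "inclusion_area_range_mm2",
        "inclusion_depth_semi_range_mm",
    }
    for key in tuple_keys & set(payload):
        payload[key] = tuple(payload[key])
    return SyntheticConfig(**payload)
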