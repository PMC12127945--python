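"""Orchestration: run the staged QC chain over a directory, build the
batch report (canonical JSON + static HTML), and rank the review subset.

Stage order is fixed: ingest -> intensity standardization -> geometry
(crop, rotation, aspect) -> annotation removal -> projection + metadata
consistency -> quality scoring. Border detection runs on the pre-window
(stored-value) image, where unexposed regions are near-black regardless
of the vendor's display window; the resulting crop is applied to the
standardized image that later stages consume.

In ``review`` mode every stage runs and nothing is dropped; in
``exclude`` mode an excluded image skips later stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import annotation as ann
from . import geometry, intensity, projection, quality
from .config import PipelineConfig
from .dicom_io import read_radiograph
from .records import (ACTION_EXCLUDE, ACTION_FLAG, ACTION_PASS, QCResult,
                      RadiographRecord)

STAGE_ORDER = ("ingest", "intensity", "geometry_crop", "geometry_rotation",
               "geometry_aspect", "annotation", "projection_consistency",
               "quality")


@dataclass
class BatchReport:
    qc_table: pd.DataFrame          # one row per image per stage
    image_table: pd.DataFrame       # one row per image: worst action, reasons
    metadata_table: pd.DataFrame
    stage_counts: pd.DataFrame
    flagged: List[str]
    config_snapshot: dict
    mode: str
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "config": self.config_snapshot,
            "qc": _df_records(self.qc_table),
            "images": _df_records(self.image_table),
            "metadata": _df_records(self.metadata_table),
            "stage_counts": _df_records(self.stage_counts.reset_index()),
            "flagged": list(self.flagged),
            "extras": self.extras,
        }


def _df_records(df: pd.DataFrame) -> list:
    out = []
    for rec in df.to_dict(orient="records"):
        clean = {}
        for k, v in rec.items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            if isinstance(v, float) and np.isnan(v):
                v = None
            clean[k] = v
        out.append(clean)
    return out


def process_record(record: RadiographRecord, config: PipelineConfig,
                   mode: str = "review",
                   model: Optional[projection.ProjectionModel] = None
                   ) -> RadiographRecord:
    """Run every stage on one already-ingested record, in place."""
    if record.image is None:
        return record  # ingest failure already recorded

    def stop() -> bool:
        return mode == "exclude" and record.excluded

    # stage 1: intensity standardization (keep the raw copy for geometry)
    raw = record.image
    record, pre, post = intensity.standardize(record)
    record.add_result(QCResult(
        stage="intensity", action=ACTION_PASS, reasons=[],
        evidence={"pre_mean": pre.mean, "pre_sd": pre.sd, "pre_cv": pre.cv,
                  "pre_entropy": pre.entropy, "post_mean": post.mean,
                  "post_sd": post.sd, "post_cv": post.cv,
                  "post_entropy": post.entropy}))
    if stop():
        return record

    # stage 2: geometry — crop detected on the raw stored-value image
    g = config.geometry
    try:
        box = geometry.detect_border_crop(raw, pad_tol=g.pad_tol,
                                          collim_threshold=g.collim_threshold)
        record.image = box.apply(record.image)
        record.log_transform(f"geometry:crop:{box.as_tuple()}")
        record.add_result(geometry.crop_result(raw, box))
    except geometry.EmptyContentError:
        record.add_result(QCResult(stage="geometry_crop", action=ACTION_EXCLUDE,
                                   reasons=["empty_content"], evidence={}))
        if stop():
            return record
    if record.image.shape[0] < 32 or record.image.shape[1] < 32:
        record.add_result(QCResult(stage="geometry_rotation",
                                   action=ACTION_EXCLUDE,
                                   reasons=["too_small_after_crop"],
                                   evidence={"shape": list(record.image.shape)}))
        return record

    if g.rotation_enabled:
        rotated, degrees = geometry.correct_rotation(record.image)
        record.image = rotated
        if degrees:
            record.log_transform(f"geometry:rotate:{degrees}")
        record.add_result(QCResult(stage="geometry_rotation", action=ACTION_PASS,
                                   reasons=[], evidence={"rotation": degrees}))

    record.add_result(geometry.aspect_ratio_check(record.image, g.aspect_bounds()))
    if stop():
        return record

    # stage 3: annotation removal
    cleaned, mask, refuse = ann.remove_annotations(record.image, config.annotation)
    if refuse is not None:
        record.add_result(refuse)
    else:
        record.image = cleaned
        if not mask.is_empty():
            record.log_transform("annotation:inpaint")
        record.add_result(QCResult(
            stage="annotation", action=ACTION_PASS, reasons=[],
            evidence={"mask_fraction": round(mask.fraction, 6),
                      "n_components": len(mask.components)}))
    if stop():
        return record

    # stage 4a: projection + metadata consistency
    declared = projection.parse_series_description(
        record.metadata.series_description)
    if model is not None:
        call = projection.predict_projection(model, record.image,
                                             config.projection.threshold)
        record.add_result(projection.consistency_check(declared, call))
    else:
        record.add_result(QCResult(
            stage="projection_consistency", action=ACTION_PASS, reasons=[],
            evidence={"declared": declared.declared, "predicted": None,
                      "score": None}))
    if stop():
        return record

    # stage 4b: quality scoring
    record.add_result(quality.assess_quality(record.image, config.quality))
    return record


def run_pipeline(input_dir: Union[str, Path],
                 config: Optional[PipelineConfig] = None,
                 mode: str = "review") -> BatchReport:
    """Process every readable image in ``input_dir`` and assemble the report."""
    if mode not in ("review", "exclude"):
        raise ValueError(f"mode must be 'review' or 'exclude', got {mode!r}")
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    paths = sorted(p for p in input_dir.rglob("*")
                   if p.suffix.lower() in (".dcm", ".png"))

    model = None
    if config.projection.model_path:
        model = projection.ProjectionModel.load(config.projection.model_path)

    records: List[RadiographRecord] = []
    ids: List[str] = []
    for p in paths:
        rec = read_radiograph(p)
        try:
            rec = process_record(rec, config, mode=mode, model=model)
        except Exception as exc:  # noqa: BLE001 - per-image fault isolation
            rec.add_result(QCResult(stage="pipeline", action=ACTION_EXCLUDE,
                                    reasons=["processing_error"],
                                    evidence={"detail": str(exc)[:200]}))
        records.append(rec)
        ids.append(p.stem)
    return build_batch_report(ids, records, config, mode)


def build_batch_report(ids: List[str], records: List[RadiographRecord],
                       config: PipelineConfig, mode: str) -> BatchReport:
    qc_rows, image_rows, meta_rows = [], [], []
    for image_id, rec in zip(ids, records):
        worst = ACTION_PASS
        reasons: List[str] = []
        for r in rec.qc_results:
            qc_rows.append({"image_id": image_id, **r.to_dict()})
            if r.action == ACTION_EXCLUDE:
                worst = ACTION_EXCLUDE
            elif r.action == ACTION_FLAG and worst != ACTION_EXCLUDE:
                worst = ACTION_FLAG
            reasons.extend(r.reasons)
        image_rows.append({"image_id": image_id, "action": worst,
                           "reasons": sorted(set(reasons)),
                           "n_flagging_stages": sum(
                               r.action == ACTION_FLAG for r in rec.qc_results)})
        meta_rows.append({"image_id": image_id, **rec.metadata.to_dict()})

    qc_table = pd.DataFrame(qc_rows, columns=["image_id", "stage", "action",
                                              "reasons", "evidence"])
    image_table = pd.DataFrame(image_rows, columns=["image_id", "action",
                                                    "reasons",
                                                    "n_flagging_stages"])
    metadata_table = pd.DataFrame(meta_rows)
    stage_counts = _stage_counts(qc_table)
    flagged = recommend_review_subset(qc_table)
    extras = _metadata_extras(metadata_table, qc_table)
    return BatchReport(qc_table=qc_table, image_table=image_table,
                       metadata_table=metadata_table, stage_counts=stage_counts,
                       flagged=flagged, config_snapshot=config.to_dict(),
                       mode=mode, extras=extras)


def _stage_counts(qc_table: pd.DataFrame) -> pd.DataFrame:
    if qc_table.empty:
        return pd.DataFrame(columns=["stage", *["n_" + a for a in
                                                (ACTION_PASS, ACTION_FLAG,
                                                 ACTION_EXCLUDE)]]).set_index("stage")
    counts = (qc_table.groupby(["stage", "action"]).size().unstack(fill_value=0))
    for a in (ACTION_PASS, ACTION_FLAG, ACTION_EXCLUDE):
        if a not in counts:
            counts[a] = 0
    counts = counts[[ACTION_PASS, ACTION_FLAG, ACTION_EXCLUDE]]
    counts.columns = ["n_" + a for a in counts.columns]
    return counts.reindex([s for s in STAGE_ORDER if s in counts.index])


def _metadata_extras(metadata_table: pd.DataFrame,
                     qc_table: pd.DataFrame) -> dict:
    extras: dict = {}
    if not metadata_table.empty:
        desc = metadata_table["series_description"].tolist()
        frac, n_with = projection.header_token_stats(desc)
        extras["header_projection_token_fraction"] = round(frac, 6)
        extras["header_projection_token_count"] = n_with
        completeness = {}
        for col in ("manufacturer", "deviation_index", "sex", "age",
                    "ethnicity", "series_description"):
            completeness[col] = round(
                float(metadata_table[col].notna().mean()), 6)
        extras["metadata_completeness"] = completeness
    cons = qc_table[qc_table["stage"] == "projection_consistency"]
    if len(cons):
        cross: Dict[str, int] = {}
        mismatches = 0
        for _, row in cons.iterrows():
            ev = row["evidence"]
            key = f"{ev.get('declared')}/{ev.get('predicted')}"
            cross[key] = cross.get(key, 0) + 1
            if row["action"] == ACTION_FLAG:
                mismatches += 1
        extras["projection_cross_table"] = dict(sorted(cross.items()))
        extras["metadata_mismatch_rate"] = round(mismatches / len(cons), 6)
    return extras


def recommend_review_subset(qc_table: pd.DataFrame,
                            budget: Optional[int] = None) -> List[str]:
    """Flagged images ordered by (number of flagging stages desc, total
    reason count desc, image ID asc); truncated to ``budget`` if given."""
    if qc_table.empty:
        return []
    flagged = qc_table[qc_table["action"] == ACTION_FLAG]
    if flagged.empty:
        return []
    scores = flagged.groupby("image_id").agg(
        n_stages=("stage", "nunique"),
        n_reasons=("reasons", lambda rs: sum(len(r) for r in rs)))
    ordered = scores.sort_values(["n_stages", "n_reasons", "image_id"],
                                 ascending=[False, False, True],
                                 kind="mergesort")
    result = list(ordered.index)
    return result[:budget] if budget is not None else result


def build_report(report: BatchReport, out_dir: Union[str, Path]) -> dict:
    """Write report.json (canonical) and report.html (static rendering).

    Returns the paths written. The JSON is byte-identical across reruns
    with the same inputs, config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.to_json_dict()
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    html_path = out_dir / "report.html"
    html_path.write_text(_render_html(report))
    return {"json": str(json_path), "html": str(html_path)}


def _render_html(report: BatchReport) -> str:
    def table(df: pd.DataFrame) -> str:
        return df.to_html(index=True, border=0)

    n = len(report.image_table)
    parts = [
        "<html><head><title>Radiograph QC report</title></head><body>",
        f"<h1>Radiograph QC report ({n} images, mode={report.mode})</h1>",
        "<h2>Per-stage outcomes</h2>", table(report.stage_counts),
        "<h2>Flagged for review</h2>",
        "<p>" + (", ".join(report.flagged) if report.flagged else "none") + "</p>",
        "<h2>Metadata</h2>",
        "<pre>" + json.dumps(report.extras, indent=1, sort_keys=True) + "</pre>",
        "</body></html>",
    ]
    return "\n".join(parts)
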