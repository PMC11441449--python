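"""Text exchange format for microperimetry exams.

The device's native export is proprietary, so this package defines its
own documented dialect:

* ``<stem>.csv`` — UTF-8, header row, one row per tested locus:
  ``subject_id, group, eye, condition, color, session, locus_id,
  x_deg, y_deg, threshold_db``.
* ``<stem>.meta.json`` — per-exam sidecar keyed by
  ``subject_id/condition/color/session`` carrying the fixation trace,
  catch trials, fixation-target intensity and test duration, plus
  optional per-subject ``island_area_mm2``.

The round trip ``read_exam_table(write_exam_table(records))`` is
lossless on every field, including the −1.0 non-seen sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exam import (
    Color, Condition, Exam, Eye, Group, Session, SubjectRecord, _valid_threshold,
)
from .grid import Grid, GridKind, Locus

CSV_COLUMNS = [
    "subject_id", "group", "eye", "condition", "color", "session",
    "locus_id", "x_deg", "y_deg", "threshold_db",
]


class ExamParseError(ValueError):
    """Malformed exam table; the message names the offending row(s)."""


def _exam_key_str(subject_id: str, condition: Condition, color: Color,
                  session: Session) -> str:
    return f"{subject_id}/{condition.value}/{color.value}/{session.value}"


def write_exam_table(records: list[SubjectRecord], path: str | Path) -> None:
    """Write records to ``<path>`` (CSV) and ``<path stem>.meta.json``."""
    path = Path(path)
    rows = []
    meta: dict = {"exams": {}, "subjects": {}}
    for rec in records:
        if rec.island_area_mm2 is not None:
            meta["subjects"][rec.subject_id] = {"island_area_mm2": rec.island_area_mm2}
        for exam in rec.exams.values():
            for locus, t in zip(exam.grid.loci, exam.thresholds):
                rows.append({
                    "subject_id": rec.subject_id,
                    "group": rec.group.value,
                    "eye": exam.eye.value,
                    "condition": exam.condition.value,
                    "color": exam.color.value,
                    "session": exam.session.value,
                    "locus_id": locus.id,
                    "x_deg": locus.x,
                    "y_deg": locus.y,
                    "threshold_db": t,
                })
            key = _exam_key_str(rec.subject_id, exam.condition, exam.color, exam.session)
            meta["exams"][key] = {
                "fixation_trace": [[x, y] for x, y in exam.fixation_trace],
                "catch_trials": [{"pressed": bool(p)} for p in exam.catch_trials],
                "fixation_target_intensity": exam.fixation_target_intensity,
                "duration_s": exam.duration_s,
                "grid_kind": exam.grid.kind.value,
                "ring_radii": list(exam.grid.ring_radii),
                "points_per_ring": exam.grid.points_per_ring,
                "ring_index": [l.ring_index for l in exam.grid.loci],
                "eye_normalized": exam.eye_normalized,
            }
    # %.17g round-trips IEEE doubles exactly through the text format
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False,
                                                   float_format="%.17g")
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_exam_table(path: str | Path) -> list[SubjectRecord]:
    """Read a CSV exam table (plus sidecar if present) into records.

    Raises
    ------
    ExamParseError
        On missing columns, out-of-range thresholds, or duplicate
        (subject, condition, color, session, locus) keys; the message
        names the offending CSV row numbers (1-based, header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ExamParseError(f"missing required columns: {missing}")

    bad = [i for i, t in zip(df.index, df["threshold_db"])
           if not _valid_threshold(float(t))]
    if bad:
        rows = [int(i) + 2 for i in bad]  # +2: header row + 1-based
        raise ExamParseError(
            f"threshold_db outside {{-1.0}} U [0, 36] at row(s) {rows}"
        )
    key_cols = ["subject_id", "condition", "color", "session", "locus_id"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise ExamParseError(f"duplicate exam/locus keys at row(s) {rows}")

    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    exam_meta = meta.get("exams", {})
    subj_meta = meta.get("subjects", {})

    records: dict[str, SubjectRecord] = {}
    grouped = df.groupby(["subject_id", "condition", "color", "session"], sort=False)
    for (sid, cond, color, session), sub in grouped:
        sid = str(sid)
        cond, color, session = Condition(cond), Color(color), Session(session)
        m = exam_meta.get(_exam_key_str(sid, cond, color, session), {})
        ring_index = m.get("ring_index", [-1] * len(sub))
        loci = tuple(
            Locus(int(lid), float(x), float(y), int(ri))
            for lid, x, y, ri in zip(sub["locus_id"], sub["x_deg"], sub["y_deg"],
                                     ring_index)
        )
        grid = Grid(loci, GridKind(m.get("grid_kind", "custom")),
                    tuple(m.get("ring_radii", ())), int(m.get("points_per_ring", 0)))
        exam = Exam(
            subject_id=sid,
            eye=Eye(sub["eye"].iloc[0]),
            condition=cond,
            color=color,
            grid=grid,
            thresholds=tuple(float(t) for t in sub["threshold_db"]),
            fixation_trace=tuple((float(x), float(y))
                                 for x, y in m.get("fixation_trace", [])),
            catch_trials=tuple(bool(c["pressed"]) for c in m.get("catch_trials", [])),
            fixation_target_intensity=float(m.get("fixation_target_intensity", 5.0)),
            duration_s=float(m.get("duration_s", float("nan"))),
            session=session,
            eye_normalized=bool(m.get("eye_normalized", False)),
        )
        if sid not in records:
            area = subj_meta.get(sid, {}).get("island_area_mm2")
            records[sid] = SubjectRecord(
                sid, Group(sub["group"].iloc[0]),
                island_area_mm2=None if area is None else float(area),
            )
        records[sid].add(exam)
    return list(records.values())
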