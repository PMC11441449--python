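"""Cohort-level statistics, structure-function correlation and the
end-to-end report pipeline.

Reports reproduce the study-style summary tables: reliability counts
and medians per group/color/session, index medians with group and
paired color comparisons, repeatability CoRs, and the Spearman
correlation of residual-island area against volume sensitivities.
All tables are plain CSV; the exclusion log lists every gated-out exam
with its reasons, and included + excluded counts always equal the
input count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exam import Color, Condition, Session, SubjectRecord
from . import indices as _indices
from . import io as _io
from . import reliability as _rel
from . import repeatability as _rep
from . import synth as _synth


def _median_iqr(values) -> tuple[float, float, float]:
    v = np.asarray(values, dtype=float)
    return (float(np.median(v)), float(np.percentile(v, 25)),
            float(np.percentile(v, 75)))


def compare_groups(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two independent samples."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(u), "p": float(p),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}


def paired_comparison(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    All-zero differences are degenerate for the signed-rank statistic;
    by policy they return p = 1.0 (no evidence of a shift).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired observations")
    d = y - x
    if np.all(d == 0.0):
        return {"W": 0.0, "p": 1.0}
    w, p = sps.wilcoxon(x, y)
    return {"W": float(w), "p": float(p)}


def structure_function(island_areas_mm2, indices_by_name: dict) -> pd.DataFrame:
    """Spearman rank correlation of island area against each index.

    ``indices_by_name`` maps an index label (e.g. ``cyan_volume``) to a
    sequence paired with ``island_areas_mm2``.  Requires n >= 4 and
    non-constant inputs.
    """
    areas = np.asarray(island_areas_mm2, float)
    if len(areas) < 4:
        raise ValueError("structure-function correlation requires n >= 4")
    if np.ptp(areas) == 0:
        raise ValueError("island areas are all ties; rank correlation undefined")
    rows = []
    for name, values in indices_by_name.items():
        v = np.asarray(values, float)
        if len(v) != len(areas):
            raise ValueError(f"{name}: length mismatch with island areas")
        if np.ptp(v) == 0:
            raise ValueError(f"{name}: all ties; rank correlation undefined")
        rho, p = sps.spearmanr(areas, v)
        rows.append({"index": name, "rho": float(rho), "p": float(p),
                     "n": len(areas)})
    return pd.DataFrame(rows)


def summarize_cohort(
    records: list[SubjectRecord],
    fl_cutoff: float = _rel.DEFAULT_FL_CUTOFF_PCT,
    rodfree_cutoff: float = _rel.DEFAULT_ROD_FREE_CUTOFF_DB,
) -> pd.DataFrame:
    """Reliability summary table: one row per (group, color, session).

    Columns mirror the standard reliability report: counts and
    percentages of exams with zero, intermediate (0 < FL < cutoff) and
    high (>= cutoff) fixation losses; BCEA63/95, P1 and P2 medians with
    IQRs; stable-fixation and rod-free-detection counts; duration
    medians.  Percentages are always consistent with the printed counts
    and the stated denominator ``n``.
    """
    if not records:
        raise ValueError("empty cohort")
    rows = []
    keys = sorted({(rec.group, *k) for rec in records for k in rec.exams},
                  key=lambda t: (t[0].value, t[1].value, t[2].value, t[3].value))
    for group, condition, color, session in keys:
        exams = [rec.exams[(condition, color, session)] for rec in records
                 if rec.group == group and (condition, color, session) in rec.exams]
        reports = [_rel.gate_exam(e, fl_cutoff, rodfree_cutoff) for e in exams]
        n = len(exams)
        fl = np.array([r.fixation_loss_pct for r in reports])
        n_zero = int(np.sum(fl == 0.0))
        n_high = int(np.sum(fl >= fl_cutoff))
        n_mid = n - n_zero - n_high
        stable = sum(r.metrics.fujii_class is _rel.FujiiClass.STABLE for r in reports)
        rodfree = [r.rod_free_detected for r in reports
                   if r.rod_free_detected is not None]
        row = {
            "group": group.value, "condition": condition.value,
            "color": color.value, "session": session.value, "n": n,
            "zero_fl_n": n_zero, "zero_fl_pct": 100.0 * n_zero / n,
            "mid_fl_n": n_mid, "mid_fl_pct": 100.0 * n_mid / n,
            "high_fl_n": n_high, "high_fl_pct": 100.0 * n_high / n,
            "stable_fixation_n": stable, "stable_fixation_pct": 100.0 * stable / n,
            "rod_free_detected_n": sum(rodfree) if rodfree else np.nan,
            "rod_free_detected_pct": 100.0 * sum(rodfree) / len(rodfree)
            if rodfree else np.nan,
            "n_excluded": sum(not r.passed for r in reports),
        }
        for name, vals in (
            ("bcea63", [r.metrics.BCEA63 for r in reports]),
            ("bcea95", [r.metrics.BCEA95 for r in reports]),
            ("p1", [r.metrics.P1 for r in reports]),
            ("p2", [r.metrics.P2 for r in reports]),
            ("duration_s", [e.duration_s for e in exams]),
        ):
            med, q1, q3 = _median_iqr(vals)
            row.update({f"{name}_median": med, f"{name}_q1": q1, f"{name}_q3": q3})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineConfig:
    """Every analysis threshold in one place, with study defaults."""

    fl_cutoff_pct: float = _rel.DEFAULT_FL_CUTOFF_PCT
    rodfree_cutoff_db: float = _rel.DEFAULT_ROD_FREE_CUTOFF_DB
    difference_thresholds_db: tuple[float, ...] = (
        0.0, _indices.DEVICE_DIFFERENCE_LIMIT_DB, _indices.TRTV_DIFFERENCE_LIMIT_DB)
    central_excluded: bool = False
    n_boot: int = 200
    seed: int = 0
    cor_formula: str = "classic"
    sentinel_policy: str = "keep"  # pointwise pairs: keep | zero | exclude
    mm_per_deg: float = 0.288

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "difference_thresholds_db" in payload:
            payload["difference_thresholds_db"] = tuple(
                payload["difference_thresholds_db"])
        return cls(**payload)


def run_pipeline(records: list[SubjectRecord], out_dir: str | Path,
                 config: PipelineConfig | None = None) -> dict[str, Path]:
    """Gate -> indices -> repeatability -> cohort summary, written as CSVs.

    Returns the mapping of table name to written path.  Deterministic
    for a given (records, config): re-running writes byte-identical
    tables.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- reliability gate + exclusion log ------------------------------
    gate_rows, excl_rows = [], []
    included: dict[str, SubjectRecord] = {}
    n_exams = 0
    for rec in records:
        for key, exam in sorted(rec.exams.items(),
                                key=lambda kv: tuple(e.value for e in kv[0])):
            n_exams += 1
            rep = _rel.gate_exam(exam, config.fl_cutoff_pct, config.rodfree_cutoff_db)
            gate_rows.append({
                "subject_id": rec.subject_id, "group": rec.group.value,
                "condition": key[0].value, "color": key[1].value,
                "session": key[2].value,
                "fixation_loss_pct": rep.fixation_loss_pct,
                "P1": rep.metrics.P1, "P2": rep.metrics.P2,
                "BCEA63": rep.metrics.BCEA63, "BCEA95": rep.metrics.BCEA95,
                "fujii_class": rep.metrics.fujii_class.value,
                "rod_free_detected": rep.rod_free_detected,
                "passed": rep.passed,
                "reasons": ";".join(r.value for r in rep.reasons),
            })
            if rep.passed:
                target = included.setdefault(
                    rec.subject_id,
                    SubjectRecord(rec.subject_id, rec.group, rec.island_area_mm2))
                target.exams[key] = exam
            else:
                excl_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group.value,
                    "condition": key[0].value, "color": key[1].value,
                    "session": key[2].value,
                    "reasons": ";".join(r.value for r in rep.reasons),
                })
    written["reliability"] = out / "reliability.csv"
    pd.DataFrame(gate_rows).to_csv(written["reliability"], index=False)
    written["exclusions"] = out / "exclusions.csv"
    pd.DataFrame(excl_rows, columns=["subject_id", "group", "condition", "color",
                                     "session", "reasons"]) \
        .to_csv(written["exclusions"], index=False)
    assert len(excl_rows) + sum(len(r.exams) for r in included.values()) == n_exams

    kept = list(included.values())

    # --- per-exam indices ----------------------------------------------
    idx_rows, pw_rows = [], []
    for rec in kept:
        for key, exam in sorted(rec.exams.items(),
                                key=lambda kv: tuple(e.value for e in kv[0])):
            si = _indices.compute_indices(exam, config.central_excluded)
            idx_rows.append({
                "subject_id": rec.subject_id, "group": rec.group.value,
                "condition": key[0].value, "color": key[1].value,
                "session": key[2].value,
                "mean_sensitivity_db": si.mean_sensitivity,
                "volume_sensitivity_db_deg2": si.volume_sensitivity,
                "temporal_mean_db": si.temporal_mean,
                "nasal_mean_db": si.nasal_mean,
                "n_non_seen": exam.n_non_seen(),
            })
            for locus, t in zip(exam.grid.loci, exam.thresholds):
                pw_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group.value,
                    "condition": key[0].value, "color": key[1].value,
                    "session": key[2].value, "locus_id": locus.id,
                    "threshold_db": t,
                })
    written["indices"] = out / "indices.csv"
    pd.DataFrame(idx_rows).to_csv(written["indices"], index=False)
    written["pointwise"] = out / "pointwise.csv"
    pd.DataFrame(pw_rows).to_csv(written["pointwise"], index=False)

    # --- cyan-red difference classification ----------------------------
    diff_rows = []
    for rec in kept:
        for session in (Session.TEST1, Session.TEST2):
            cy = rec.get(Condition.SCOTOPIC, Color.CYAN, session)
            rd = rec.get(Condition.SCOTOPIC, Color.RED, session)
            if cy is None or rd is None:
                continue
            for thr in config.difference_thresholds_db:
                dm = _indices.classify_difference(cy, rd, thr)
                for lid, d, cls in zip(dm.locus_ids, dm.cyan_minus_red, dm.classes):
                    diff_rows.append({
                        "subject_id": rec.subject_id, "session": session.value,
                        "threshold_db": thr, "locus_id": lid,
                        "cyan_minus_red_db": d,
                        "class": cls.value if cls is not None else "",
                    })
    written["differences"] = out / "differences.csv"
    pd.DataFrame(diff_rows).to_csv(written["differences"], index=False)

    # --- repeatability --------------------------------------------------
    rep_rows = []
    retest = [r for r in kept
              if any(k[2] is Session.TEST2 for k in r.exams)]
    for color in (Color.CYAN, Color.RED):
        pw = _rep.paired_pointwise(retest, color, sentinel=config.sentinel_policy)
        if not pw.empty and pw["subject"].nunique() >= 2:
            res = _rep.rm_bland_altman(pw, n_boot=config.n_boot, seed=config.seed,
                                       cor_formula=config.cor_formula)
            exact, within2 = _rep.agreement_rates(pw)
            rep_rows.append(_rep_row(color, "pointwise", res,
                                     exact=exact, within2=within2))
        for index in ("mean", "volume"):
            pairs = _rep.paired_summary(retest, color, index,
                                        config.central_excluded)
            if len(pairs) >= 2:
                res = _rep.standard_bland_altman(pairs, n_boot=config.n_boot,
                                                 seed=config.seed,
                                                 cor_formula=config.cor_formula)
                rep_rows.append(_rep_row(color, index, res))
    try:
        combined = _rep.cyan_red_combined_cor(retest, n_boot=config.n_boot,
                                              seed=config.seed,
                                              cor_formula=config.cor_formula)
        rep_rows.append(_rep_row(None, "cyan_red_pointwise", combined))
    except ValueError:
        pass
    written["repeatability"] = out / "repeatability.csv"
    pd.DataFrame(rep_rows).to_csv(written["repeatability"], index=False)

    # --- cohort summary + group stats ----------------------------------
    written["reliability_summary"] = out / "reliability_summary.csv"
    summarize_cohort(records, config.fl_cutoff_pct, config.rodfree_cutoff_db) \
        .to_csv(written["reliability_summary"], index=False)

    idx_df = pd.DataFrame(idx_rows)
    stats_rows = []
    t1 = idx_df[idx_df["session"] == "test1"]
    for color in ("cyan_505nm", "red_627nm"):
        for col in ("mean_sensitivity_db", "volume_sensitivity_db_deg2"):
            a = t1[(t1.group == "healthy") & (t1.color == color)][col]
            b = t1[(t1.group == "choroideremia") & (t1.color == color)][col]
            if len(a) >= 2 and len(b) >= 2:
                cmp = compare_groups(a, b)
                stats_rows.append({"comparison": "healthy_vs_choroideremia",
                                   "color": color, "index": col, **cmp})
    for grp in ("healthy", "choroideremia"):
        sub = t1[t1.group == grp].pivot_table(index="subject_id", columns="color",
                                              values="mean_sensitivity_db")
        if {"cyan_505nm", "red_627nm"} <= set(sub.columns) and len(sub) >= 2:
            pc = paired_comparison(sub["cyan_505nm"], sub["red_627nm"])
            stats_rows.append({"comparison": "cyan_vs_red_paired", "color": "",
                               "index": f"mean_sensitivity_db[{grp}]", **pc})
    written["statistics"] = out / "statistics.csv"
    pd.DataFrame(stats_rows).to_csv(written["statistics"], index=False)

    # --- structure-function ---------------------------------------------
    chm = [r for r in kept if r.island_area_mm2 is not None]
    sf_inputs: dict[str, list[float]] = {"cyan_volume": [], "red_volume": [],
                                         "cyan_minus_red_volume": []}
    areas = []
    for rec in chm:
        cy = rec.get(Condition.SCOTOPIC, Color.CYAN, Session.TEST1)
        rd = rec.get(Condition.SCOTOPIC, Color.RED, Session.TEST1)
        if cy is None or rd is None:
            continue
        vc = _indices.volume_sensitivity(cy)
        vr = _indices.volume_sensitivity(rd)
        areas.append(rec.island_area_mm2)
        sf_inputs["cyan_volume"].append(vc)
        sf_inputs["red_volume"].append(vr)
        sf_inputs["cyan_minus_red_volume"].append(vc - vr)
    if len(areas) >= 4:
        try:
            sf = structure_function(areas, sf_inputs)
        except ValueError:
            sf = pd.DataFrame(columns=["index", "rho", "p", "n"])
        written["structure_function"] = out / "structure_function.csv"
        sf.to_csv(written["structure_function"], index=False)

    manifest = {name: str(p.name) for name, p in written.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return written


def _rep_row(color: Color | None, index: str,
             res: _rep.RepeatabilityResult, **extra) -> dict:
    row = {
        "color": color.value if color is not None else "cyan_minus_red",
        "index": index, "bias": res.bias, "sd_within": res.sd_within,
        "sd_between": res.sd_between, "cor": res.cor,
        "loa_low": res.loa_low, "loa_high": res.loa_high,
        "n_subjects": res.n_subjects, "n_pairs": res.n_pairs,
        "model": res.model,
    }
    for key, (lo, hi) in res.ci.items():
        row[f"{key}_ci_low"] = lo
        row[f"{key}_ci_high"] = hi
    row.update(extra)
    return row


def simulate_and_run(cohort_config: _synth.SyntheticCohortConfig | None,
                     out_dir: str | Path,
                     pipeline_config: PipelineConfig | None = None,
                     write_exams: bool = False) -> dict[str, Path]:
    """Convenience: simulate a cohort, optionally export it, run the
    pipeline."""
    cohort_config = cohort_config or _synth.SyntheticCohortConfig()
    records = _synth.simulate_cohort(cohort_config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_exams:
        _io.write_exam_table(records, out / "exams.csv")
    return run_pipeline(records, out, pipeline_config)
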