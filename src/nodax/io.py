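"""Readers, writers and validation for cohort directories and reports.

A cohort directory holds four UTF-8, comma-separated tables with header rows:
``subjects.csv``, ``lymph_nodes.csv``, ``joints.csv`` and ``visits.csv``.
Units are fixed by the column names (axes in cm, cortical width in mm, ESR in
mm/1h, VAS in mm); readers refuse columns whose names suggest a different
unit rather than guessing a conversion. Validation failures refuse the run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .grading import JOINT_SITES, SIDES, CalibrationModel
from .tables import (
    JOINT_COLUMNS,
    NODE_COLUMNS,
    OPTIONAL_VISIT_COLUMNS,
    SUBJECT_COLUMNS,
    VISIT_COLUMNS,
    CohortTables,
)

__all__ = [
    "ValidationReport",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_calibration",
    "write_calibration",
    "write_report",
    "render_text_report",
    "load_frame",
    "load_roi",
]

DEFAULT_VISIT_WEEKS = (0, 4, 24)

#: measurement column stems and their fixed unit suffix; any other suffix on
#: the same stem is refused as unit-ambiguous.
_UNIT_STEMS = {
    "long_axis": "long_axis_cm",
    "short_axis": "short_axis_cm",
    "cortical_width": "cortical_width_mm",
    "esr": "esr_mm_h",
    "vas_ptga": "vas_ptga_mm",
    "rf_titer": "rf_titer_u_ml",
    "acpa_titer": "acpa_titer_u_ml",
}


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def error(self, table: str, row, fieldname: str, message: str) -> None:
        self.errors.append({"table": table, "row": row, "field": fieldname, "message": message})

    def warn(self, table: str, row, fieldname: str, message: str) -> None:
        self.warnings.append({"table": table, "row": row, "field": fieldname, "message": message})

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for e in self.errors[:50]:
            lines.append(f"  ERROR {e['table']}[{e['row']}].{e['field']}: {e['message']}")
        for w in self.warnings[:20]:
            lines.append(f"  warning {w['table']}[{w['row']}].{w['field']}: {w['message']}")
        return "\n".join(lines)


class CohortValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        super().__init__("cohort validation failed:\n" + report.summary())
        self.report = report


def _check_columns(df: pd.DataFrame, required: Iterable[str], table: str, report: ValidationReport) -> bool:
    ok = True
    for col in required:
        if col not in df.columns:
            report.error(table, "-", col, "required column missing")
            ok = False
    for col in df.columns:
        for stem, canonical in _UNIT_STEMS.items():
            if col.startswith(stem) and col != canonical and col not in OPTIONAL_VISIT_COLUMNS:
                report.error(
                    table,
                    "-",
                    col,
                    f"unit-ambiguous column name; expected {canonical!r} (units are fixed)",
                )
                ok = False
    return ok


def read_cohort(
    directory, visit_weeks: tuple = DEFAULT_VISIT_WEEKS, strict: bool = True
) -> CohortTables:
    """Read and validate a cohort directory.

    Raises :class:`CohortValidationError` when validation errors are present
    (unless ``strict=False``, in which case the report is attached and the
    caller decides). The validation report is attached to the returned
    tables either way.
    """
    directory = Path(directory)
    report = ValidationReport()
    frames = {}
    for name in ("subjects", "lymph_nodes", "joints", "visits"):
        path = directory / f"{name}.csv"
        if not path.exists():
            report.error(name, "-", "-", f"missing file {path}")
            continue
        frames[name] = pd.read_csv(path, encoding="utf-8")
    if report.errors:
        raise CohortValidationError(report)

    subjects, nodes, joints, visits = (
        frames["subjects"],
        frames["lymph_nodes"],
        frames["joints"],
        frames["visits"],
    )

    _check_columns(subjects, SUBJECT_COLUMNS, "subjects", report)
    _check_columns(nodes, NODE_COLUMNS, "lymph_nodes", report)
    _check_columns(joints, JOINT_COLUMNS, "joints", report)
    _check_columns(visits, VISIT_COLUMNS, "visits", report)
    if report.errors:
        raise CohortValidationError(report)

    # subjects
    if subjects["subject_id"].duplicated().any():
        dupes = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].tolist()
        report.error("subjects", "-", "subject_id", f"duplicate ids {dupes}")
    known = set(subjects["subject_id"])
    for i, row in subjects.iterrows():
        if row["group"] not in ("RA", "control"):
            report.error("subjects", i, "group", f"must be RA|control, got {row['group']!r}")
        if row["dominant_side"] not in SIDES:
            report.error("subjects", i, "dominant_side", f"must be one of {SIDES}")

    # lymph nodes
    for i, row in nodes.iterrows():
        if row["subject_id"] not in known:
            report.error("lymph_nodes", i, "subject_id", "unknown subject")
        if row["side"] not in SIDES:
            report.error("lymph_nodes", i, "side", f"must be one of {SIDES}")
        if int(row["visit_week"]) not in visit_weeks:
            report.error("lymph_nodes", i, "visit_week", f"must be one of {visit_weeks}")
        la, sa = row["long_axis_cm"], row["short_axis_cm"]
        if not (sa > 0 and la > 0):
            report.error("lymph_nodes", i, "short_axis_cm", "axes must be positive")
        elif sa > la:
            report.error(
                "lymph_nodes", i, "short_axis_cm",
                f"short axis ({sa}) exceeds long axis ({la})",
            )
        if row["cortical_width_mm"] < 0:
            report.error("lymph_nodes", i, "cortical_width_mm", "must be >= 0")
        count = row["pd_cortical_signal_count"]
        if not (pd.isna(count) or (float(count) >= 0 and float(count) == int(count))):
            report.error(
                "lymph_nodes", i, "pd_cortical_signal_count",
                f"must be a nonnegative integer or empty, got {count!r}",
            )

    # joints
    key = joints[["subject_id", "visit_week", "side", "joint_id"]].apply(tuple, axis=1)
    for i in joints.index[key.duplicated()]:
        report.error("joints", i, "joint_id", f"duplicate joint site {tuple(joints.loc[i, ['subject_id', 'visit_week', 'side', 'joint_id']])}")
    for i, row in joints.iterrows():
        if row["subject_id"] not in known:
            report.error("joints", i, "subject_id", "unknown subject")
        if row["side"] not in SIDES:
            report.error("joints", i, "side", f"must be one of {SIDES}")
        if row["joint_id"] not in JOINT_SITES:
            report.error("joints", i, "joint_id", f"must be one of {JOINT_SITES}")
        for col in ("gs_grade", "pd_grade"):
            g = row[col]
            if not (0 <= g <= 3 and float(g) == int(g)):
                report.error("joints", i, col, f"must be an integer grade 0..3, got {g!r}")

    # visits
    for i, row in visits.iterrows():
        if row["subject_id"] not in known:
            report.error("visits", i, "subject_id", "unknown subject")
        if int(row["visit_week"]) not in visit_weeks:
            report.error("visits", i, "visit_week", f"must be one of {visit_weeks}")
        for col, hi in (("tjc28", 28), ("sjc28", 28)):
            if not (0 <= row[col] <= hi):
                report.error("visits", i, col, f"must lie in 0..{hi}")
        if not (row["esr_mm_h"] > 0):
            report.error("visits", i, "esr_mm_h", "must be > 0")
        if not (0 <= row["vas_ptga_mm"] <= 100):
            report.error("visits", i, "vas_ptga_mm", "must lie in 0..100")

    # every RA subject needs a baseline visit row
    ra_ids = set(subjects.loc[subjects["group"] == "RA", "subject_id"])
    with_baseline = set(visits.loc[visits["visit_week"] == 0, "subject_id"])
    for sid in sorted(ra_ids - with_baseline):
        report.error("visits", "-", "visit_week", f"RA subject {sid} has no baseline (week 0) visit")

    tables = CohortTables(
        subjects=subjects, lymph_nodes=nodes, joints=joints, visits=visits, validation=report
    )
    if strict and not report.ok:
        raise CohortValidationError(report)
    return tables


def write_cohort(tables: CohortTables, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables.subjects.to_csv(directory / "subjects.csv", index=False)
    tables.lymph_nodes.to_csv(directory / "lymph_nodes.csv", index=False)
    tables.joints.to_csv(directory / "joints.csv", index=False)
    tables.visits.to_csv(directory / "visits.csv", index=False)


# ---------------------------------------------------------------------------
# calibration files (flat key = value text)
# ---------------------------------------------------------------------------


def read_calibration(path) -> CalibrationModel:
    values = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        values[key.strip()] = raw.strip()
    kwargs = {}
    if "uln_volume_cm3" in values:
        kwargs["uln_volume_cm3"] = float(values.pop("uln_volume_cm3"))
    if "uln_cortical_mm" in values:
        kwargs["uln_cortical_mm"] = float(values.pop("uln_cortical_mm"))
    if "lncw_step_mm" in values:
        kwargs["lncw_step_mm"] = float(values.pop("lncw_step_mm"))
    if "pd_count_bins" in values:
        kwargs["pd_count_bins"] = tuple(int(x) for x in values.pop("pd_count_bins").split(","))
    if values:
        raise ValueError(f"unknown calibration keys: {sorted(values)}")
    return CalibrationModel(**kwargs)


def write_calibration(calibration: CalibrationModel, path) -> None:
    Path(path).write_text(
        "uln_volume_cm3 = {:.6g}\n"
        "uln_cortical_mm = {:.6g}\n"
        "lncw_step_mm = {:.6g}\n"
        "pd_count_bins = {}\n".format(
            calibration.uln_volume_cm3,
            calibration.uln_cortical_mm,
            calibration.lncw_step_mm,
            ",".join(str(b) for b in calibration.pd_count_bins),
        ),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# analysis reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    """Round floats to a fixed precision and map non-finite values to None."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if not math.isfinite(f):
            return None
        return float(f"{f:.6g}")
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(report: dict, path, fmt: str = "json") -> None:
    """Serialize an analysis report deterministically.

    JSON output is byte-stable for equal reports (sorted keys, fixed float
    precision); ``fmt="text"`` writes the human-readable rendering, in which
    missing statistics appear as ``undefined``.
    """
    path = Path(path)
    if fmt == "json":
        payload = json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
        path.write_text(payload, encoding="utf-8")
    elif fmt == "text":
        path.write_text(render_text_report(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _fmt(value, digits=4) -> str:
    if value is None:
        return "undefined"
    if isinstance(value, float):
        if not math.isfinite(value):
            return "undefined"
        return f"{value:.{digits}g}"
    return str(value)


def render_text_report(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines = ["nodax analysis report", "=" * 21, ""]
    meta = {k: report[k] for k in ("n_subjects", "n_ra", "n_controls", "seed", "cohort_hash") if k in report}
    for k, v in meta.items():
        lines.append(f"{k}: {_fmt(v)}")
    if "group_comparisons" in report:
        lines += ["", "Group comparisons (RA vs control, baseline)", "-" * 44]
        for row in report["group_comparisons"]:
            lines.append(
                f"  {row['measure']:<18} {row['test']:<12} p={_fmt(row['p_value'])} "
                f"RA median {_fmt(row['ra_median'])} vs control {_fmt(row['control_median'])}"
            )
    if "correlation_table" in report:
        lines += ["", "Spearman correlations (baseline)", "-" * 32]
        for row in report["correlation_table"]:
            if row.get("note"):
                lines.append(f"  {row['ln_index']} vs {row['covariate']} [{row['block']}]: skipped ({row['note']})")
            else:
                lines.append(
                    f"  {row['ln_index']} vs {row['covariate']:<18} [{row['block']:<13}] "
                    f"rho={_fmt(row['rho'], 3)} (95% CI {_fmt(row['ci_low'], 3)} to {_fmt(row['ci_high'], 3)}) p={_fmt(row['p_value'])}"
                )
    if "longitudinal" in report:
        lines += ["", "Longitudinal response (weeks 0/4/24)", "-" * 37]
        for name, entry in report["longitudinal"].items():
            lines.append(
                f"  {name}: n={entry['n']} Friedman chi2={_fmt(entry.get('friedman_chi2'))} "
                f"p={_fmt(entry.get('friedman_p'))} post-hoc {entry.get('posthoc_p')}"
            )
    if "responsiveness" in report:
        lines += ["", "External responsiveness (delta regressions)", "-" * 43]
        for row in report["responsiveness"]:
            lines.append(
                f"  week {row['week']:<3} {row['ln_index']:<12} on {row['regressor']:<22} "
                f"R2={_fmt(row.get('r2'), 3)} p={_fmt(row.get('p_value'))}"
            )
    if "prediction" in report:
        lines += ["", "Prediction of good EULAR response (baseline LNPD index = 0)", "-" * 59]
        pred = report["prediction"]
        if "note" in pred:
            lines.append(f"  skipped: {pred['note']}")
        else:
            for model, entry in pred.items():
                lines.append(
                    f"  {model}: OR={_fmt(entry['odds_ratio'], 3)} "
                    f"(95% CI {_fmt(entry['ci_low'], 3)}-{_fmt(entry['ci_high'], 3)}) "
                    f"p={_fmt(entry['p_value'])} [{entry['method']}]"
                    + (" SEPARATION" if entry.get("separation") else "")
                )
    lines.append("")
    return "\n".join(lines)


def cohort_hash(directory) -> str:
    """Short content hash of the four CSVs, for reproducibility logging."""
    digest = hashlib.sha256()
    for name in ("subjects", "lymph_nodes", "joints", "visits"):
        path = Path(directory) / f"{name}.csv"
        if path.exists():
            digest.update(path.read_bytes())
    return digest.hexdigest()[:12]


# ---------------------------------------------------------------------------
# image inputs
# ---------------------------------------------------------------------------


def load_frame(path) -> np.ndarray:
    """Load an 8-bit RGB frame from PNG/TIFF."""
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def load_roi(path, shape=None) -> np.ndarray:
    """Load an ROI as a binary mask image or a plain-text polygon file.

    Polygon files carry one "x,y" pair per line (pixel coordinates, origin
    top-left, 0-based) and require ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() in (".txt", ".poly"):
        if shape is None:
            raise ValueError("polygon ROI requires the frame shape")
        from .dia import polygon_to_mask

        vertices = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line:
                continue
            x, y = line.split(",")
            vertices.append((float(x), float(y)))
        return polygon_to_mask(vertices, shape)
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("L")) > 127
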