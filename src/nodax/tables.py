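"""Linked cohort tables consumed by the grading and statistics pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["CohortTables", "SUBJECT_COLUMNS", "NODE_COLUMNS", "JOINT_COLUMNS", "VISIT_COLUMNS"]

SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "age_years",
    "sex",
    "dominant_side",
    "disease_duration_months",
    "rf_positive",
    "rf_titer_u_ml",
    "acpa_positive",
    "acpa_titer_u_ml",
    "on_glucocorticoids",
)
NODE_COLUMNS = (
    "subject_id",
    "visit_week",
    "side",
    "long_axis_cm",
    "short_axis_cm",
    "cortical_width_mm",
    "pd_cortical_signal_count",
    "palpable",
)
JOINT_COLUMNS = ("subject_id", "visit_week", "side", "joint_id", "gs_grade", "pd_grade")
VISIT_COLUMNS = (
    "subject_id",
    "visit_week",
    "tjc28",
    "sjc28",
    "esr_mm_h",
    "vas_ptga_mm",
    "das28",
)
#: Optional side-restricted clinical joint counts (nondominant arm), used by
#: the ipsilateral correlation panel when present.
OPTIONAL_VISIT_COLUMNS = ("tjc_nondominant", "sjc_nondominant")


@dataclass
class CohortTables:
    """The four linked tables of one cohort, keyed by subject_id (+ visit_week).

    ``truth`` optionally carries generator ground truth (never serialized);
    it is absent for cohorts read from disk.
    """

    subjects: pd.DataFrame
    lymph_nodes: pd.DataFrame
    joints: pd.DataFrame
    visits: pd.DataFrame
    truth: Optional[dict] = field(default=None, repr=False, compare=False)
    validation: Optional[object] = field(default=None, repr=False, compare=False)

    def baseline_nodes(self) -> pd.DataFrame:
        return self.lymph_nodes[self.lymph_nodes["visit_week"] == 0]

    def ra_ids(self) -> list:
        return list(self.subjects.loc[self.subjects["group"] == "RA", "subject_id"])

    def control_ids(self) -> list:
        return list(self.subjects.loc[self.subjects["group"] == "control", "subject_id"])
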