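"""Semiquantitative grading of axillary lymph-node and hand/wrist joint sonography.

Three nodal parameters are measured per lymph node and converted into ordinal
0-3 grades against control-derived thresholds:

* **LNV** — lymph node volume, estimated from the two sonographic axes by the
  ellipsoid formula ``V = 4/3 * pi * a**2 * b`` with ``a`` the short-axis
  radius and ``b`` the long-axis radius (cm³).
* **LNCW** — lymph node cortical width, the maximum cortical measurement from
  the medulla-cortex interface to the capsule (mm).
* **LNPD** — cortical power-Doppler signal, graded from the number of
  discrete PD-positive signals detected in the cortex.

Grade 0 is anchored at the upper limit of normal (ULN), defined as the
control-group mean + 2 SD. Per subject and visit, each parameter yields a
*cumulative index*: the maximum grade in the right axilla plus the maximum
grade in the left axilla (range 0-6). Subjects without detectable nodes score
0 by convention.

Synovitis is graded on the same 0-3 ordinal scale for gray-scale (GS) and
power-Doppler (PD) findings over a 12-joint bilateral assessment (wrist
complex + MCP I-V per side), summed into 0-36 cumulative joint indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GradingValidationError",
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "LymphNodeRecord",
    "GradeSet",
    "SubjectIndices",
    "JointRecord",
    "JointIndices",
    "JOINT_SITES",
    "SIDES",
    "ellipsoid_volume",
    "calibrate_uln",
    "grade_lnv",
    "grade_lncw",
    "grade_lnpd",
    "grade_node",
    "cumulative_index",
    "joint_indices",
]

SIDES = ("right", "left")
#: The 12-joint assessment model: six graded sites per side. The wrist complex
#: (radiocarpal, ulnocarpal, radioulnar, midcarpal) is graded as one site.
JOINT_SITES = ("wrist", "mcp1", "mcp2", "mcp3", "mcp4", "mcp5")
GRADE_MAX = 3
INDEX_MAX = 2 * GRADE_MAX  # per-parameter cumulative index range 0-6
JOINT_INDEX_MAX = 2 * len(JOINT_SITES) * GRADE_MAX  # 0-36


class GradingValidationError(ValueError):
    """A measurement or record violates its physical or scale constraints."""


def _as_float(value, name: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise GradingValidationError(f"{name} must be numeric, got {value!r}") from exc


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationModel:
    """Control-derived thresholds anchoring grade 0 at the upper limit of normal.

    Parameters
    ----------
    uln_volume_cm3
        ULN for nodal volume (cm³). Grade bands are multiples of this value:
        0 ≤ 1·ULN < 1 ≤ 2·ULN < 2 ≤ 3·ULN < 3.
    uln_cortical_mm
        ULN for cortical width (mm); grade bands step by ``lncw_step_mm``.
    lncw_step_mm
        Width of each cortical grade band above the ULN (mm).
    pd_count_bins
        Inclusive upper count bounds of PD grades 0, 1 and 2; counts above
        the last bound are grade 3. The default ``(1, 3, 5)`` encodes the
        bands 0-1 / 2-3 / 4-5 / ≥6.
    """

    uln_volume_cm3: float = 0.65
    uln_cortical_mm: float = 4.0
    lncw_step_mm: float = 1.0
    pd_count_bins: tuple[int, int, int] = (1, 3, 5)

    def __post_init__(self) -> None:
        if not (self.uln_volume_cm3 > 0):
            raise GradingValidationError("uln_volume_cm3 must be > 0")
        if not (self.uln_cortical_mm > 0):
            raise GradingValidationError("uln_cortical_mm must be > 0")
        if not (self.lncw_step_mm > 0):
            raise GradingValidationError("lncw_step_mm must be > 0")
        bins = tuple(self.pd_count_bins)
        if len(bins) != 3:
            raise GradingValidationError("pd_count_bins must have 3 boundaries")
        if any(int(b) != b or b < 0 for b in bins):
            raise GradingValidationError("pd_count_bins must be nonnegative integers")
        if not (bins[0] < bins[1] < bins[2]):
            raise GradingValidationError("pd_count_bins must be strictly increasing")
        object.__setattr__(self, "pd_count_bins", tuple(int(b) for b in bins))

    @classmethod
    def from_controls(
        cls,
        control_volumes_cm3: Sequence[float],
        control_cortical_mm: Sequence[float],
        lncw_step_mm: float = 1.0,
        pd_count_bins: tuple[int, int, int] = (1, 3, 5),
    ) -> "CalibrationModel":
        """Build a calibration from a user-supplied control cohort (mean + 2 SD)."""
        return cls(
            uln_volume_cm3=calibrate_uln(control_volumes_cm3),
            uln_cortical_mm=calibrate_uln(control_cortical_mm),
            lncw_step_mm=lncw_step_mm,
            pd_count_bins=pd_count_bins,
        )


#: Thresholds shipped as constants from the originating study (volume ULN
#: 0.65 cm³, cortical ULN 4 mm, 1 mm cortical steps, PD bands 0-1/2-3/4-5/≥6).
DEFAULT_CALIBRATION = CalibrationModel()


def calibrate_uln(control_values: Sequence[float]) -> float:
    """Upper limit of normal from a control sample: mean + 2·SD.

    SD is the sample standard deviation (n−1 denominator), the convention for
    reference-interval estimation from a small control group. Requires at
    least two values (SD is undefined otherwise).
    """
    values = np.asarray(list(control_values), dtype=float)
    if values.size < 2:
        raise GradingValidationError(
            f"calibrate_uln needs >= 2 control values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise GradingValidationError("control values must be finite")
    return float(values.mean() + 2.0 * values.std(ddof=1))


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LymphNodeRecord:
    """Raw sonographic measurements of one lymph node at one visit.

    ``pd_cortical_signal_count`` may be ``None`` when the Doppler video for
    the node is missing; such nodes are excluded from the LNPD side maximum.
    """

    subject_id: str
    visit_week: int
    side: str
    long_axis_cm: float
    short_axis_cm: float
    cortical_width_mm: float
    pd_cortical_signal_count: Optional[int]
    palpable: bool = False

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise GradingValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        la = _as_float(self.long_axis_cm, "long_axis_cm")
        sa = _as_float(self.short_axis_cm, "short_axis_cm")
        if not (sa > 0):
            raise GradingValidationError(f"short_axis_cm must be > 0, got {sa}")
        if sa > la:
            raise GradingValidationError(
                f"short_axis_cm ({sa}) must not exceed long_axis_cm ({la})"
            )
        cw = _as_float(self.cortical_width_mm, "cortical_width_mm")
        if cw < 0:
            raise GradingValidationError(f"cortical_width_mm must be >= 0, got {cw}")
        count = self.pd_cortical_signal_count
        if count is not None:
            if int(count) != count or count < 0:
                raise GradingValidationError(
                    f"pd_cortical_signal_count must be a nonnegative integer, got {count!r}"
                )

    @property
    def volume_cm3(self) -> float:
        return ellipsoid_volume(self.long_axis_cm, self.short_axis_cm)


@dataclass(frozen=True)
class GradeSet:
    """Ordinal 0-3 grades of one node (LNPD grade ``None`` when PD missing)."""

    lnv_grade: int
    lncw_grade: int
    lnpd_grade: Optional[int]
    volume_cm3: float
    side: str


@dataclass(frozen=True)
class SubjectIndices:
    """Bilateral cumulative indices (0-6) for one subject-visit.

    ``lnpd_index`` is ``None`` when nodes were detected but every node on both
    sides lacks a PD assessment; 0 is reserved for "no detectable node" or
    observed absent flow.
    """

    subject_id: str
    visit_week: int
    lnv_index: int
    lncw_index: int
    lnpd_index: Optional[int]
    n_detected_nodes: int


@dataclass(frozen=True)
class JointRecord:
    """One graded joint site (GS and PD, each 0-3) for a subject-visit-side."""

    subject_id: str
    visit_week: int
    side: str
    joint_id: str
    gs_grade: int
    pd_grade: int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise GradingValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.joint_id not in JOINT_SITES:
            raise GradingValidationError(
                f"joint_id must be one of {JOINT_SITES}, got {self.joint_id!r}"
            )
        for name in ("gs_grade", "pd_grade"):
            g = getattr(self, name)
            if int(g) != g or not (0 <= g <= GRADE_MAX):
                raise GradingValidationError(f"{name} must be an integer in 0..3, got {g!r}")


@dataclass(frozen=True)
class JointIndices:
    """12-joint cumulative indices: bilateral 0-36 sums and per-side 0-18 sums."""

    subject_id: str
    visit_week: int
    gs12_index: int
    pd12_index: int
    gs_side_index: dict
    pd_side_index: dict


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ellipsoid_volume(long_axis_cm, short_axis_cm):
    """Nodal volume (cm³) by the ellipsoid formula 4/3·π·a²·b.

    ``a`` is the short-axis radius (SA/2) and ``b`` the long-axis radius
    (LA/2), i.e. a prolate spheroid of revolution about the long axis.
    Accepts scalars or numpy arrays.
    """
    la = np.asarray(long_axis_cm, dtype=float)
    sa = np.asarray(short_axis_cm, dtype=float)
    if np.any(~(sa > 0)):
        raise GradingValidationError("short_axis_cm must be > 0")
    if np.any(~(la > 0)):
        raise GradingValidationError("long_axis_cm must be > 0")
    if np.any(sa > la):
        raise GradingValidationError("short_axis_cm must not exceed long_axis_cm")
    volume = (4.0 / 3.0) * math.pi * (sa / 2.0) ** 2 * (la / 2.0)
    if np.ndim(volume) == 0:
        return float(volume)
    return volume


def _band_grade(ratio_checks) -> int:
    return int(sum(ratio_checks))


def grade_lnv(volume_cm3, calibration: CalibrationModel = DEFAULT_CALIBRATION):
    """LNV grade: 0 ≤ ULN; 1 in (1, 2]·ULN; 2 in (2, 3]·ULN; 3 above 3·ULN.

    Bands are closed on their upper bound. Accepts scalars or arrays.
    """
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(~(v > 0)):
        raise GradingValidationError("volume_cm3 must be > 0")
    r = v / calibration.uln_volume_cm3
    grade = (r > 1).astype(int) + (r > 2) + (r > 3)
    if np.ndim(grade) == 0:
        return int(grade)
    return grade


def grade_lncw(cortical_width_mm, calibration: CalibrationModel = DEFAULT_CALIBRATION):
    """LNCW grade: 0 ≤ ULN; then 1-mm (``lncw_step_mm``) bands, upper-inclusive."""
    w = np.asarray(cortical_width_mm, dtype=float)
    if np.any(w < 0):
        raise GradingValidationError("cortical_width_mm must be >= 0")
    uln = calibration.uln_cortical_mm
    step = calibration.lncw_step_mm
    grade = (w > uln).astype(int) + (w > uln + step) + (w > uln + 2 * step)
    if np.ndim(grade) == 0:
        return int(grade)
    return grade


def grade_lnpd(
    pd_cortical_signal_count, calibration: CalibrationModel = DEFAULT_CALIBRATION
):
    """LNPD grade from the count of PD+ cortical signals (0-1 / 2-3 / 4-5 / ≥6)."""
    c = np.asarray(pd_cortical_signal_count)
    if not np.issubdtype(c.dtype, np.number) or np.any(c != np.floor(c)) or np.any(c < 0):
        raise GradingValidationError(
            "pd_cortical_signal_count must be a nonnegative integer"
        )
    b0, b1, b2 = calibration.pd_count_bins
    grade = (c > b0).astype(int) + (c > b1) + (c > b2)
    if np.ndim(grade) == 0:
        return int(grade)
    return grade


def grade_node(
    record: LymphNodeRecord, calibration: CalibrationModel = DEFAULT_CALIBRATION
) -> GradeSet:
    """Grade all three parameters of one node."""
    volume = record.volume_cm3
    count = record.pd_cortical_signal_count
    return GradeSet(
        lnv_grade=grade_lnv(volume, calibration),
        lncw_grade=grade_lncw(record.cortical_width_mm, calibration),
        lnpd_grade=None if count is None else grade_lnpd(count, calibration),
        volume_cm3=volume,
        side=record.side,
    )


def cumulative_index(
    nodes: Iterable[LymphNodeRecord],
    subject_id: Optional[str] = None,
    visit_week: Optional[int] = None,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
) -> SubjectIndices:
    """Bilateral cumulative indices for one subject-visit.

    For each parameter the index is the maximum grade in the right axilla plus
    the maximum grade in the left axilla. A side with no detected nodes
    contributes 0; a subject with no detectable nodes scores 0 on all indices.
    Nodes with missing PD assessment are excluded from the LNPD side maximum;
    if every node on both sides is missing PD, the LNPD index is ``None``.

    ``subject_id``/``visit_week`` are required when ``nodes`` is empty and are
    otherwise checked for consistency with the records.
    """
    nodes = list(nodes)
    if nodes:
        ids = {(n.subject_id, n.visit_week) for n in nodes}
        if len(ids) > 1:
            raise GradingValidationError(
                f"nodes span multiple subject-visits: {sorted(ids)}"
            )
        (sid, week) = next(iter(ids))
        if subject_id is not None and subject_id != sid:
            raise GradingValidationError(
                f"subject_id {subject_id!r} does not match node records ({sid!r})"
            )
        if visit_week is not None and visit_week != week:
            raise GradingValidationError(
                f"visit_week {visit_week!r} does not match node records ({week!r})"
            )
        subject_id, visit_week = sid, week
    elif subject_id is None or visit_week is None:
        raise GradingValidationError(
            "subject_id and visit_week are required when no nodes are supplied"
        )

    if not nodes:
        return SubjectIndices(subject_id, visit_week, 0, 0, 0, 0)

    grades = [grade_node(n, calibration) for n in nodes]
    lnv = sum(
        max((g.lnv_grade for g in grades if g.side == side), default=0) for side in SIDES
    )
    lncw = sum(
        max((g.lncw_grade for g in grades if g.side == side), default=0) for side in SIDES
    )
    pd_grades = [g for g in grades if g.lnpd_grade is not None]
    if not pd_grades:
        lnpd: Optional[int] = None
    else:
        lnpd = sum(
            max((g.lnpd_grade for g in pd_grades if g.side == side), default=0)
            for side in SIDES
        )
    return SubjectIndices(subject_id, visit_week, int(lnv), int(lncw), lnpd, len(nodes))


def joint_indices(
    joints: Iterable[JointRecord],
    subject_id: Optional[str] = None,
    visit_week: Optional[int] = None,
) -> JointIndices:
    """12-joint cumulative GS and PD indices (bilateral sums of 0-3 grades).

    Side indices are the sums restricted to each side (0-18 each); the
    bilateral index is their sum (0-36). Duplicate joint sites within a side
    are rejected.
    """
    joints = list(joints)
    if joints:
        ids = {(j.subject_id, j.visit_week) for j in joints}
        if len(ids) > 1:
            raise GradingValidationError(
                f"joints span multiple subject-visits: {sorted(ids)}"
            )
        subject_id, visit_week = next(iter(ids))
    elif subject_id is None or visit_week is None:
        raise GradingValidationError(
            "subject_id and visit_week are required when no joints are supplied"
        )

    seen = set()
    for j in joints:
        key = (j.side, j.joint_id)
        if key in seen:
            raise GradingValidationError(f"duplicate joint site {key} in subject-visit")
        seen.add(key)

    gs_side = {side: sum(j.gs_grade for j in joints if j.side == side) for side in SIDES}
    pd_side = {side: sum(j.pd_grade for j in joints if j.side == side) for side in SIDES}
    return JointIndices(
        subject_id=subject_id,
        visit_week=visit_week,
        gs12_index=int(sum(gs_side.values())),
        pd12_index=int(sum(pd_side.values())),
        gs_side_index={k: int(v) for k, v in gs_side.items()},
        pd_side_index={k: int(v) for k, v in pd_side.items()},
    )
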