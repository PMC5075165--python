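"""Synthetic cohorts and power-Doppler image fixtures.

The generator emits cohorts with the statistical structure the analysis
pipeline assumes, emulating the study conditions of the motivating trial:

* 20 healthy controls and 40 csDMARD-refractory RA patients with active
  disease (DAS28 >= 3.2), with demographic, serologic and clinical marginals
  anchored to the published baseline table;
* 0-9 sonographically detectable axillary nodes per subject (median 2-3),
  control node volumes calibrated so that a large control sample yields an
  upper limit of normal (mean + 2 SD) of about 0.65 cm3, cortical widths
  with ULN about 4 mm;
* an "LN-abnormal" RA subgroup (about 40 %) whose nodes exceed the control
  thresholds, driven by a shared per-subject reactivity latent that couples
  volume, cortical width and cortical PD signal within a patient;
* PD+ synovitis in about 62.5 % of RA patients, with ipsilateral coupling
  between nondominant-arm joint PD burden and that side's nodal reactivity;
* three visits (weeks 0/4/24) on TNF-inhibitor treatment with an early joint
  PD response and a late (week-24-only) LN response restricted to the
  abnormal subgroup;
* a responder/non-responder structure in which the bilateral absence of
  cortical LN PD signal at baseline (LNPD index = 0) is strongly negatively
  associated with good EULAR response.

Per-visit sonographic measurements are fresh draws around each node's latent
state: re-scanning at a later visit is an independent measurement, not a
noisy copy of the baseline numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .clinical import das28_esr
from .dia import PDFrame
from .grading import DEFAULT_CALIBRATION, JOINT_SITES, SIDES, CalibrationModel, grade_lnpd
from .tables import CohortTables

__all__ = ["GeneratorConfig", "generate_cohort", "generate_pd_frame"]


class GeneratorError(ValueError):
    """Inconsistent generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the cohort generator (defaults = study conditions)."""

    seed: int = 0
    n_controls: int = 20
    n_ra: int = 40
    n_followup: int = 35

    # detectable-node count distribution (support 0..max_nodes)
    ln_count_mean_control: float = 2.3
    ln_count_mean_ra: float = 3.2
    p_no_nodes_control: float = 0.15
    p_no_nodes_ra: float = 0.10
    max_nodes: int = 9

    # control-like per-node measurement distributions
    volume_median_cm3: float = 0.18
    volume_log_sigma: float = 0.75  # gives mean + 2 SD ~ 0.653 cm3
    cortical_mean_mm: float = 2.7
    cortical_sd_mm: float = 0.65  # mean + 2 SD = 4.0 mm
    pd_zero_inflation: float = 0.6
    pd_base_rate: float = 0.5
    # mild RA-wide cortical PD elevation (also outside the abnormal subgroup)
    ra_pd_zero_inflation: float = 0.6
    ra_pd_base_rate: float = 0.55

    # re-measurement (re-scan) noise between visits
    volume_log_noise: float = 0.12
    cortical_noise_mm: float = 0.35

    # RA nodal reactivity structure
    abnormal_subgroup_fraction: float = 0.40
    abnormal_burden_slope: float = 0.10  # membership probability per nondominant joint burden unit
    reactivity_floor: float = 0.8  # minimum reactivity of an abnormal subject
    reactivity_shape: float = 1.8
    reactivity_scale: float = 0.45
    abnormal_volume_scale: float = 2.0  # log-volume shift per reactivity unit
    abnormal_cortical_shift_mm: float = 2.2  # mm per reactivity unit
    abnormal_pd_rate: float = 3.5  # extra Poisson PD signals per reactivity unit
    ipsilateral_coupling: float = 1.0  # nondominant-side reactivity per burden unit
    #: drainage-driven PD elevation on the nondominant side for every RA
    #: subject: extra Poisson PD signals per unit of nondominant joint burden
    #: (vascular flow responds to drainage before structural hypertrophy does)
    pd_ipsi_rate: float = 3.0

    # joint synovitis structure
    pd_synovitis_fraction: float = 0.625
    joint_pd_burden_shape: float = 0.8  # per side; sides are independent
    joint_pd_burden_scale: float = 2.5
    gs_burden_shape: float = 7.0
    gs_burden_scale: float = 1.7
    gs_pd_coupling: float = 0.5

    # treatment dynamics: fraction of burden/reactivity removed at each visit
    joint_effect_w4_responder: float = 0.65
    joint_effect_w4_other: float = 0.45
    joint_effect_w24_responder: float = 0.55
    joint_effect_w24_other: float = 0.25
    gs_effect_w4: float = 0.10
    gs_effect_w24: float = 0.18
    ln_effect_w4: float = 0.0
    #: week-24 LN reactivity removal = base + coupling * realized relative
    #: reduction of the subject's 12-joint PD index (drainage load falls with
    #: the joints it drains), capped at 0.92
    ln_effect_w24_base: float = 0.55
    ln_effect_w24_joint_coupling: float = 0.65

    # response structure
    responder_fraction: float = 0.55
    lnpd0_nonresponse_strength: float = -3.1  # log-odds of good response

    # demographics / clinical marginals
    dominant_right_fraction: float = 0.9
    age_mean_ra: float = 54.6
    age_sd_ra: float = 14.0
    female_fraction_ra: float = 0.80
    age_mean_control: float = 53.2
    age_sd_control: float = 17.2
    female_fraction_control: float = 0.75
    duration_median_months: float = 38.0
    duration_log_sigma: float = 1.34
    rf_positive_fraction: float = 0.65
    rf_titer_median: float = 85.0
    rf_titer_log_sigma: float = 1.38
    acpa_positive_fraction: float = 0.675
    acpa_titer_median: float = 66.0
    acpa_titer_log_sigma: float = 1.75
    acpa_titer_cap: float = 340.0
    gc_fraction: float = 0.775
    tjc_median: float = 8.0
    tjc_log_sigma: float = 0.6
    sjc_median: float = 4.0
    sjc_log_sigma: float = 0.65
    esr_median: float = 22.0
    esr_log_sigma: float = 0.5
    vas_mean: float = 64.0
    vas_sd: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "p_no_nodes_control",
            "p_no_nodes_ra",
            "abnormal_subgroup_fraction",
            "pd_synovitis_fraction",
            "responder_fraction",
            "dominant_right_fraction",
            "female_fraction_ra",
            "female_fraction_control",
            "rf_positive_fraction",
            "acpa_positive_fraction",
            "gc_fraction",
            "pd_zero_inflation",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise GeneratorError(f"{name} must lie in [0, 1], got {value}")
        if self.n_controls < 0 or self.n_ra < 1:
            raise GeneratorError("cohort sizes must be positive")
        if not (0 <= self.n_followup <= self.n_ra):
            raise GeneratorError("n_followup must lie in 0..n_ra")
        if 0.0 < self.abnormal_subgroup_fraction and (
            self.abnormal_subgroup_fraction * self.n_ra < 1.0
        ):
            raise GeneratorError(
                "abnormal_subgroup_fraction too small to realize with n_ra subjects"
            )
        for name in ("volume_log_sigma", "cortical_mean_mm", "cortical_sd_mm"):
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def null_cross_sectional(self) -> "GeneratorConfig":
        """Zero every cross-sectional effect: no abnormal subgroup (hence no
        RA-vs-control nodal difference and no ipsilateral coupling) and no
        association between baseline LNPD and response."""
        return self.replace(
            abnormal_subgroup_fraction=0.0,
            lnpd0_nonresponse_strength=0.0,
            ra_pd_zero_inflation=self.pd_zero_inflation,
            ra_pd_base_rate=self.pd_base_rate,
            pd_ipsi_rate=0.0,
            ln_count_mean_ra=self.ln_count_mean_control,
            p_no_nodes_ra=self.p_no_nodes_control,
        )

    def null_longitudinal(self) -> "GeneratorConfig":
        """Zero the treatment effect on LN indices (abnormal subgroup kept)."""
        return self.replace(
            ln_effect_w4=0.0, ln_effect_w24_base=0.0, ln_effect_w24_joint_coupling=0.0
        )


def _count_pmf(mean: float, p_zero: float, max_nodes: int) -> np.ndarray:
    support = np.arange(max_nodes + 1)
    pmf = stats.poisson.pmf(support, mean)
    pmf /= pmf.sum()
    pmf[1:] *= (1.0 - p_zero) / pmf[1:].sum()
    pmf[0] = p_zero
    return pmf


def _axes_from_volume(volume: float, aspect: float) -> tuple[float, float]:
    # V = pi/6 * SA^2 * LA with aspect = SA/LA
    sa = (6.0 * volume * aspect / math.pi) ** (1.0 / 3.0)
    return sa / aspect, sa  # (LA, SA)


def _flow_rate(rng: np.random.Generator, p_zero: float, mean_rate: float) -> float:
    """Persistent cortical flow propensity of one node.

    A fraction ``p_zero`` of nodes has no detectable baseline flow; the rest
    carry an exponential rate with overall mean ``mean_rate``. Per-visit
    signal counts are Poisson draws around this persistent rate, so repeated
    scans of the same node are correlated, as in real re-examinations.
    """
    if rng.random() < p_zero:
        return 0.0
    m = mean_rate / (1.0 - p_zero)
    return float(rng.gamma(2.0, m / 2.0))


def _solve_component_scale(tjc, sjc, esr, vas, target: float) -> float:
    """Scale factor on the baseline clinical components reproducing a target DAS28."""

    def f(s):
        return (
            das28_esr(
                min(28.0, tjc * s),
                min(28.0, sjc * s),
                max(2.0, esr * s),
                min(100.0, vas * s),
            )
            - target
        )

    lo, hi = 0.02, 4.0
    if f(lo) >= 0:
        return lo
    if f(hi) <= 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> CohortTables:
    """Generate one synthetic cohort (deterministic given ``config.seed``)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    control_ids = [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    ra_ids = [f"R{i + 1:02d}" for i in range(cfg.n_ra)]

    # ------------------------------------------------------------------ subjects
    subject_rows = []
    for sid in control_ids:
        subject_rows.append(
            {
                "subject_id": sid,
                "group": "control",
                "age_years": round(float(np.clip(rng.normal(cfg.age_mean_control, cfg.age_sd_control), 20, 85)), 1),
                "sex": "F" if rng.random() < cfg.female_fraction_control else "M",
                "dominant_side": "right" if rng.random() < cfg.dominant_right_fraction else "left",
                "disease_duration_months": np.nan,
                "rf_positive": 0,
                "rf_titer_u_ml": np.nan,
                "acpa_positive": 0,
                "acpa_titer_u_ml": np.nan,
                "on_glucocorticoids": 0,
            }
        )
    for sid in ra_ids:
        rf_pos = rng.random() < cfg.rf_positive_fraction
        acpa_pos = rng.random() < cfg.acpa_positive_fraction
        # seronegative subjects carry a measured titer below the assay cutoff
        rf_titer = round(
            float(np.exp(np.log(cfg.rf_titer_median) + cfg.rf_titer_log_sigma * rng.standard_normal()))
            if rf_pos
            else float(rng.uniform(2.0, 14.0)),
            1,
        )
        acpa_titer = round(
            float(min(cfg.acpa_titer_cap, np.exp(np.log(cfg.acpa_titer_median) + cfg.acpa_titer_log_sigma * rng.standard_normal())))
            if acpa_pos
            else float(rng.uniform(0.5, 6.0)),
            1,
        )
        subject_rows.append(
            {
                "subject_id": sid,
                "group": "RA",
                "age_years": round(float(np.clip(rng.normal(cfg.age_mean_ra, cfg.age_sd_ra), 20, 85)), 1),
                "sex": "F" if rng.random() < cfg.female_fraction_ra else "M",
                "dominant_side": "right" if rng.random() < cfg.dominant_right_fraction else "left",
                "disease_duration_months": round(float(np.exp(np.log(cfg.duration_median_months) + cfg.duration_log_sigma * rng.standard_normal())), 1),
                "rf_positive": int(rf_pos),
                "rf_titer_u_ml": rf_titer,
                "acpa_positive": int(acpa_pos),
                "acpa_titer_u_ml": acpa_titer,
                "on_glucocorticoids": int(rng.random() < cfg.gc_fraction),
            }
        )
    subjects = pd.DataFrame(subject_rows)
    nondominant = {
        row["subject_id"]: ("left" if row["dominant_side"] == "right" else "right")
        for row in subject_rows
    }

    # ------------------------------------------------------- RA latent structure
    # synovial PD activity is drawn per arm, independently across arms,
    # calibrated so that the fraction with PD+ synovitis in at least one arm
    # equals pd_synovitis_fraction; within-patient side dominance is strongly
    # asymmetric and the only joint-LN coupling is the injected ipsilateral one
    q_side = 1.0 - math.sqrt(1.0 - cfg.pd_synovitis_fraction)
    syn_nd = rng.random(cfg.n_ra) < q_side
    syn_dom = rng.random(cfg.n_ra) < q_side
    synovitis = syn_nd | syn_dom
    burden_nd = rng.gamma(cfg.joint_pd_burden_shape, cfg.joint_pd_burden_scale, cfg.n_ra) * syn_nd
    burden_dom = rng.gamma(cfg.joint_pd_burden_shape, cfg.joint_pd_burden_scale, cfg.n_ra) * syn_dom
    pd_burden = burden_nd + burden_dom
    gs_burden = rng.gamma(cfg.gs_burden_shape, cfg.gs_burden_scale, cfg.n_ra) + cfg.gs_pd_coupling * pd_burden

    caf = cfg.abnormal_subgroup_fraction
    if caf > 0:
        # nodal reactivity follows drainage from the nondominant arm, so
        # membership tracks the nondominant-side joint burden specifically
        mean_burden = cfg.joint_pd_burden_shape * cfg.joint_pd_burden_scale * q_side
        p_abnormal = np.clip(caf + cfg.abnormal_burden_slope * (burden_nd - mean_burden), 0.02, 0.95)
    else:
        p_abnormal = np.zeros(cfg.n_ra)
    abnormal = rng.random(cfg.n_ra) < p_abnormal
    reactivity = np.where(
        abnormal,
        cfg.reactivity_floor + rng.gamma(cfg.reactivity_shape, cfg.reactivity_scale, cfg.n_ra),
        0.0,
    )

    # --------------------------------------------------------------- lymph nodes
    k_cw = (cfg.cortical_mean_mm / cfg.cortical_sd_mm) ** 2
    theta_cw = cfg.cortical_sd_mm**2 / cfg.cortical_mean_mm
    pmf_control = _count_pmf(cfg.ln_count_mean_control, cfg.p_no_nodes_control, cfg.max_nodes)
    pmf_ra = _count_pmf(cfg.ln_count_mean_ra, cfg.p_no_nodes_ra, cfg.max_nodes)

    nodes = {}  # subject_id -> list of persistent node dicts
    for gi, sid in enumerate(control_ids + ra_ids):
        is_ra = gi >= cfg.n_controls
        ri = gi - cfg.n_controls
        count = int(rng.choice(len(pmf_ra), p=pmf_ra if is_ra else pmf_control))
        # both axillae are scanned: detected nodes split near-evenly by side
        sides = [SIDES[(i + int(rng.integers(2))) % 2] for i in range(count)]
        per_subject = []
        for side in sides:
            severity = 0.0
            pd_ipsi = 0.0
            if is_ra:
                severity = reactivity[ri]
                if side == nondominant[sid]:
                    pd_ipsi = cfg.pd_ipsi_rate * (burden_nd[ri] / 2.5)
                    if abnormal[ri]:
                        severity += cfg.ipsilateral_coupling * (burden_nd[ri] / 2.5)
            per_subject.append(
                {
                    "side": side,
                    "base_log_volume": math.log(cfg.volume_median_cm3) + cfg.volume_log_sigma * rng.standard_normal(),
                    "base_cortical": rng.gamma(k_cw, theta_cw),
                    "severity": severity,
                    "pd_ipsi": pd_ipsi,
                    "base_pd_rate": _flow_rate(
                        rng,
                        cfg.ra_pd_zero_inflation if is_ra else cfg.pd_zero_inflation,
                        cfg.ra_pd_base_rate if is_ra else cfg.pd_base_rate,
                    ),
                }
            )
        nodes[sid] = per_subject

    def measure_node(node: dict, effect: float) -> dict:
        sev = node["severity"] * (1.0 - effect)
        log_v = node["base_log_volume"] + cfg.abnormal_volume_scale * sev + cfg.volume_log_noise * rng.standard_normal()
        volume = math.exp(log_v)
        la, sa = _axes_from_volume(volume, rng.uniform(0.35, 0.7))
        cw = max(0.2, node["base_cortical"] + cfg.abnormal_cortical_shift_mm * sev + cfg.cortical_noise_mm * rng.standard_normal())
        rate = node["base_pd_rate"] + cfg.abnormal_pd_rate * sev + node["pd_ipsi"] * (1.0 - effect)
        count = int(rng.poisson(rate)) if rate > 0 else 0
        return {
            "side": node["side"],
            "long_axis_cm": round(la, 3),
            "short_axis_cm": round(sa, 3),
            "cortical_width_mm": round(cw, 2),
            "pd_cortical_signal_count": count,
            "palpable": int(volume > 0.9 or rng.random() < 0.04),
        }

    node_rows = []
    baseline_counts: dict[str, list] = {}  # per-subject (side, pd count) at week 0
    for sid in control_ids + ra_ids:
        baseline_counts[sid] = []
        for node in nodes[sid]:
            m = measure_node(node, 0.0)
            baseline_counts[sid].append((m["side"], m["pd_cortical_signal_count"]))
            node_rows.append({"subject_id": sid, "visit_week": 0, **m})

    # baseline LNPD index (bilateral sum of per-side max grades)
    lnpd_index0 = {}
    for sid in ra_ids:
        idx = 0
        for side in SIDES:
            grades = [grade_lnpd(c) for s, c in baseline_counts[sid] if s == side]
            idx += max(grades, default=0)
        lnpd_index0[sid] = idx

    # ------------------------------------------------------ response assignment
    followup_ids = sorted(str(s) for s in rng.choice(ra_ids, size=cfg.n_followup, replace=False))
    lnpd0 = np.array([1.0 if lnpd_index0[sid] == 0 else 0.0 for sid in followup_ids])
    beta1 = cfg.lnpd0_nonresponse_strength

    def marginal(beta0):
        return float(np.mean(expit(beta0 + beta1 * lnpd0))) - cfg.responder_fraction

    if cfg.n_followup > 0:
        beta0 = float(optimize.brentq(marginal, -15.0, 15.0))
        good = rng.random(cfg.n_followup) < expit(beta0 + beta1 * lnpd0)
    else:
        good = np.array([], dtype=bool)
    responder = dict(zip(followup_ids, (bool(g) for g in good)))

    # --------------------------------------------------------------------- joints
    joint_rows = []
    baseline_joint = {}  # (sid, side, site) -> (gs, pd)
    pd12_baseline = {}
    for ri, sid in enumerate(ra_ids):
        total = 0
        for side in SIDES:
            side_burden = burden_nd[ri] if side == nondominant[sid] else burden_dom[ri]
            lam_pd = side_burden / len(JOINT_SITES)
            for site in JOINT_SITES:
                gs = int(min(3, rng.poisson(gs_burden[ri] / 12.0)))
                pdg = int(min(3, rng.poisson(lam_pd)))
                total += pdg
                baseline_joint[(sid, side, site)] = (gs, pdg)
                joint_rows.append(
                    {
                        "subject_id": sid,
                        "visit_week": 0,
                        "side": side,
                        "joint_id": site,
                        "gs_grade": gs,
                        "pd_grade": pdg,
                    }
                )
        pd12_baseline[sid] = total
    pd12_week24 = {}
    for sid in followup_ids:
        resp = responder[sid]
        for week in (4, 24):
            if week == 4:
                f_pd = cfg.joint_effect_w4_responder if resp else cfg.joint_effect_w4_other
                f_gs = cfg.gs_effect_w4 * (1.0 if resp else 0.5)
            else:
                f_pd = cfg.joint_effect_w24_responder if resp else cfg.joint_effect_w24_other
                f_gs = cfg.gs_effect_w24 * (1.0 if resp else 0.5)
            total = 0
            for side in SIDES:
                for site in JOINT_SITES:
                    gs0, pd0 = baseline_joint[(sid, side, site)]
                    pd_v = int(rng.binomial(pd0, 1.0 - f_pd))
                    total += pd_v
                    joint_rows.append(
                        {
                            "subject_id": sid,
                            "visit_week": week,
                            "side": side,
                            "joint_id": site,
                            "gs_grade": int(rng.binomial(gs0, 1.0 - f_gs)),
                            "pd_grade": pd_v,
                        }
                    )
            if week == 24:
                pd12_week24[sid] = total
    joints = pd.DataFrame(joint_rows)

    # ---------------------------------------------- follow-up node measurements
    # the week-24 LN effect tracks the realized joint PD reduction: drainage
    # load on the node falls with the joints it drains
    for sid in followup_ids:
        base24 = pd12_baseline[sid]
        rel_drop = (
            max(0.0, base24 - pd12_week24[sid]) / base24 if base24 > 0 else 0.0
        )
        effect24 = min(0.95, cfg.ln_effect_w24_base + cfg.ln_effect_w24_joint_coupling * rel_drop)
        if cfg.ln_effect_w24_base == 0.0 and cfg.ln_effect_w24_joint_coupling == 0.0:
            effect24 = 0.0
        for week, effect in ((4, cfg.ln_effect_w4), (24, effect24)):
            for node in nodes[sid]:
                node_rows.append({"subject_id": sid, "visit_week": week, **measure_node(node, effect)})
    from .tables import NODE_COLUMNS

    lymph_nodes = pd.DataFrame(node_rows, columns=list(NODE_COLUMNS))

    # --------------------------------------------------------------------- visits
    visit_rows = []
    baseline_clin = {}
    _nd_clin_share = {}
    for ri, sid in enumerate(ra_ids):
        for _ in range(60):
            tjc = float(np.exp(np.log(cfg.tjc_median) + cfg.tjc_log_sigma * rng.standard_normal()))
            sjc = float(np.exp(np.log(cfg.sjc_median) + cfg.sjc_log_sigma * rng.standard_normal()))
            esr = float(np.exp(np.log(cfg.esr_median) + cfg.esr_log_sigma * rng.standard_normal()))
            vas = float(np.clip(rng.normal(cfg.vas_mean, cfg.vas_sd), 5, 100))
            tjc_i, sjc_i = int(np.clip(round(tjc), 0, 28)), int(np.clip(round(sjc), 0, 28))
            esr_r, vas_i = max(2.0, round(esr, 1)), int(round(vas))
            if das28_esr(tjc_i, sjc_i, esr_r, vas_i) >= 3.25:
                break
        das0 = das28_esr(tjc_i, sjc_i, esr_r, vas_i)
        baseline_clin[sid] = (tjc_i, sjc_i, esr_r, vas_i, das0)
        total_burden = burden_nd[ri] + burden_dom[ri]
        share = float(np.clip(burden_nd[ri] / total_burden, 0.1, 0.9)) if total_burden > 0 else 0.5
        _nd_clin_share[sid] = share
        visit_rows.append(
            {
                "subject_id": sid,
                "visit_week": 0,
                "tjc28": tjc_i,
                "sjc28": sjc_i,
                "esr_mm_h": esr_r,
                "vas_ptga_mm": vas_i,
                "das28": round(das0, 2),
                "tjc_nondominant": int(rng.binomial(tjc_i, share)),
                "sjc_nondominant": int(rng.binomial(sjc_i, share)),
            }
        )

    for sid in followup_ids:
        tjc0, sjc0, esr0, vas0, das0 = baseline_clin[sid]
        if responder[sid]:
            target24 = max(1.2, min(3.05, das0 - 1.35) - rng.uniform(0.0, 0.9))
        else:
            target24 = float(np.clip(das0 - rng.uniform(-0.4, 1.05), 1.0, 9.4))
        target4 = float(np.clip(das0 - 0.55 * (das0 - target24) + rng.normal(0.0, 0.3), 0.9, 9.6))
        for week, target in ((4, target4), (24, target24)):
            s = _solve_component_scale(tjc0, sjc0, esr0, vas0, target)
            tjc_i = int(np.clip(round(tjc0 * s), 0, 28))
            sjc_i = int(np.clip(round(sjc0 * s), 0, 28))
            esr_r = max(2.0, round(esr0 * s, 1))
            vas_i = int(np.clip(round(vas0 * s), 0, 100))
            visit_rows.append(
                {
                    "subject_id": sid,
                    "visit_week": week,
                    "tjc28": tjc_i,
                    "sjc28": sjc_i,
                    "esr_mm_h": esr_r,
                    "vas_ptga_mm": vas_i,
                    "das28": round(das28_esr(tjc_i, sjc_i, esr_r, vas_i), 2),
                    "tjc_nondominant": int(rng.binomial(tjc_i, _nd_clin_share[sid])),
                    "sjc_nondominant": int(rng.binomial(sjc_i, _nd_clin_share[sid])),
                }
            )
    visits = pd.DataFrame(visit_rows).sort_values(["subject_id", "visit_week"], kind="stable").reset_index(drop=True)

    truth = {
        "config": cfg,
        "abnormal": {sid: bool(abnormal[i]) for i, sid in enumerate(ra_ids)},
        "reactivity": {sid: float(reactivity[i]) for i, sid in enumerate(ra_ids)},
        "synovitis": {sid: bool(synovitis[i]) for i, sid in enumerate(ra_ids)},
        "joint_pd_burden": {sid: float(pd_burden[i]) for i, sid in enumerate(ra_ids)},
        "followup_ids": list(followup_ids),
        "responder": responder,
        "lnpd_index0": lnpd_index0,
    }
    return CohortTables(
        subjects=subjects,
        lymph_nodes=lymph_nodes,
        joints=joints,
        visits=visits,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# synthetic power-Doppler frames
# ---------------------------------------------------------------------------

#: Saturated overlay palette (all chroma >= 150, well above any threshold).
_PALETTE = ((235, 90, 40), (250, 140, 50), (220, 60, 30), (255, 170, 60))

#: Blob-count support per grade, matching the count bands of the PD grading.
_GRADE_BLOBS = {0: (0, 1), 1: (2, 3), 2: (4, 5), 3: (6, 7, 8)}


def generate_pd_frame(
    grade: int,
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
) -> tuple[PDFrame, dict]:
    """Synthetic PD snapshot of a lymph node with ground truth.

    Draws a grayscale elliptical node (hypoechoic cortex around a brighter
    medulla) on a dark speckle background, then paints a grade-banded number
    of saturated color blobs inside the cortex. Returns the frame (ROI = the
    node ellipse) plus a truth dict with the blob count and the exact number
    of painted pixels, for counting-oracle tests. All non-painted pixels are
    pure gray, so chroma classification recovers the painted set exactly.
    """
    if grade not in _GRADE_BLOBS:
        raise GeneratorError(f"grade must be in 0..3, got {grade!r}")
    rng = np.random.default_rng(seed)
    h, w = shape
    from skimage.draw import disk, ellipse

    gray = rng.integers(10, 38, size=(h, w)).astype(np.uint8)
    roi = np.zeros((h, w), dtype=bool)
    ry = int(rng.integers(max(10, h // 4), max(12, int(h * 0.3))))
    rx = int(rng.integers(max(12, w // 3), max(14, int(w * 0.42))))
    rr, cc = ellipse(h // 2, w // 2, ry, rx, shape=(h, w))
    roi[rr, cc] = True
    inner = np.zeros((h, w), dtype=bool)
    rr, cc = ellipse(h // 2, w // 2, max(2, int(ry * 0.5)), max(2, int(rx * 0.55)), shape=(h, w))
    inner[rr, cc] = True
    cortex = roi & ~inner

    gray[cortex] = (55 + 12 * rng.standard_normal(int(cortex.sum()))).clip(30, 90).astype(np.uint8)
    gray[inner] = (120 + 15 * rng.standard_normal(int(inner.sum()))).clip(80, 170).astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)

    n_blobs = int(rng.choice(_GRADE_BLOBS[grade]))
    painted = np.zeros((h, w), dtype=bool)
    cortex_coords = np.argwhere(cortex)
    for _ in range(n_blobs):
        cy, cx = cortex_coords[rng.integers(len(cortex_coords))]
        radius = int(rng.integers(2, 5))
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        keep = roi[rr, cc]
        rr, cc = rr[keep], cc[keep]
        color = _PALETTE[int(rng.integers(len(_PALETTE)))]
        for ch in range(3):
            pixels[rr, cc, ch] = color[ch]
        painted[rr, cc] = True

    frame = PDFrame(pixels=pixels, roi_mask=roi, nominal_grade=grade)
    truth = {"n_blobs": n_blobs, "painted_pixels": int(painted.sum())}
    return frame, truth
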