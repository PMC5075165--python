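"""Cross-sectional and longitudinal statistical analyses of a cohort.

The pipeline reproduces, on any conforming cohort, the analysis battery of
the motivating study design:

* **Group comparisons** (RA vs control) of the LN cumulative indices and of
  the continuous nodal parameters (per-subject maxima) by two-sided
  Mann-Whitney tests; detection/palpability proportions by chi-square with an
  exact (Fisher) fallback when any expected cell is below 5.
* **Correlation panel** at baseline: Spearman's rho with Fisher-z 95 %
  confidence intervals between each LN index and autoantibody titers,
  tender/swollen counts and the 12-joint GS/PD indices, including
  ipsilateral (nondominant-arm) and contralateral blocks.
* **Longitudinal response**: Friedman tests over weeks 0/4/24 restricted to
  subjects with baseline values above the control range, with exact
  signed-rank post-hoc comparisons (weeks 4 and 24 vs baseline) under Holm
  multiplicity control (Conover's variance-pooled post-hoc is selectable).
* **External responsiveness**: OLS of LN index change scores on ipsilateral
  joint PD change and on DAS28 change, separately at weeks 4 and 24. Change
  scores are baseline − follow-up, so positive values indicate reduction.
* **Outcome prediction**: logistic regression of good (vs moderate/none)
  EULAR response on the indicator of a baseline LNPD index of 0, adjusted
  for baseline joint PD (model 1) and additionally for age, sex, disease
  duration, glucocorticoid co-medication and baseline DAS28 (model 2).
  Complete separation is detected and reported, with a Firth (Jeffreys-prior
  penalized) fit as the flagged fallback.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clinical import das28_esr, eular_response
from .grading import (
    DEFAULT_CALIBRATION,
    SIDES,
    CalibrationModel,
    ellipsoid_volume,
    grade_lncw,
    grade_lnpd,
    grade_lnv,
)
from .tables import CohortTables

__all__ = [
    "AnalysisError",
    "subject_ln_indices",
    "joint_index_table",
    "spearman_ci",
    "holm_adjust",
    "signed_rank_exact_p",
    "conover_friedman_posthoc",
    "compare_groups",
    "correlation_table",
    "longitudinal_response",
    "external_responsiveness",
    "predict_response",
    "firth_logit",
    "analyze_cohort",
]


class AnalysisError(ValueError):
    """The cohort cannot support the requested analysis."""


# ---------------------------------------------------------------------------
# derived per-subject tables
# ---------------------------------------------------------------------------


def subject_ln_indices(
    cohort: CohortTables, calibration: CalibrationModel = DEFAULT_CALIBRATION
) -> pd.DataFrame:
    """Per subject-visit LN summary: cumulative indices, continuous maxima and
    nondominant-side grades.

    Covers every in-scope subject-visit (controls at week 0, RA at the weeks
    present in the visits table, at minimum week 0); subjects without
    detectable nodes score 0 with ``n_detected_nodes`` 0.
    """
    subjects = cohort.subjects
    nodes = cohort.lymph_nodes.copy()
    key = ["subject_id", "visit_week"]

    # in-scope subject-visits: controls at week 0, RA at week 0 plus the
    # weeks present in the visits table
    ra_ids = sorted(cohort.ra_ids())
    parts = [
        pd.DataFrame({"subject_id": cohort.control_ids(), "visit_week": 0}),
        pd.DataFrame({"subject_id": ra_ids, "visit_week": 0}),
    ]
    if len(cohort.visits):
        ra_weeks = cohort.visits.loc[
            cohort.visits["subject_id"].isin(ra_ids), key
        ].astype({"visit_week": int})
        parts.append(ra_weeks)
    frame = pd.concat(parts, ignore_index=True).drop_duplicates(key, ignore_index=True)

    if len(nodes):
        nodes["volume_cm3"] = ellipsoid_volume(
            nodes["long_axis_cm"].to_numpy(), nodes["short_axis_cm"].to_numpy()
        )
        nodes["lnv_grade"] = grade_lnv(nodes["volume_cm3"].to_numpy(), calibration)
        nodes["lncw_grade"] = grade_lncw(nodes["cortical_width_mm"].to_numpy(), calibration)
        counts = nodes["pd_cortical_signal_count"]
        has_pd = counts.notna().to_numpy()
        lnpd = np.full(len(nodes), np.nan)
        if has_pd.any():
            lnpd[has_pd] = grade_lnpd(counts.to_numpy(dtype=float)[has_pd], calibration)
        nodes["lnpd_grade"] = lnpd
    else:
        for col in ("volume_cm3", "lnv_grade", "lncw_grade", "lnpd_grade"):
            nodes[col] = pd.Series(dtype=float)

    dominant = subjects.set_index("subject_id")["dominant_side"]
    nodes = nodes.merge(dominant.rename("dominant_side"), left_on="subject_id", right_index=True, how="left")
    nodes["is_nondominant"] = nodes["side"] != nodes["dominant_side"]
    nodes["palpable"] = nodes["palpable"].astype(bool)

    out = frame.copy()
    if len(nodes):
        # per-side maxima summed over the sides present; a side with no
        # detected nodes contributes 0 (it is simply absent from the sum)
        side_max = nodes.groupby(key + ["side"], sort=False)[
            ["lnv_grade", "lncw_grade"]
        ].max()
        index_sum = side_max.groupby(key).sum()
        index_sum.columns = ["lnv_index", "lncw_index"]
        # LNPD: nodes lacking a PD assessment drop out of the side maximum
        # (NaN-skipping max); a side where every node lacks it yields NaN and
        # is skipped in the sum, and only when both sides are NaN does the
        # subject's index stay missing (min_count=1)
        side_pd = nodes.groupby(key + ["side"], sort=False)["lnpd_grade"].max()
        lnpd_sum = side_pd.groupby(key).sum(min_count=1).rename("lnpd_index")
        per_sv = nodes.groupby(key, sort=False).agg(
            n_detected_nodes=("side", "size"),
            max_volume_cm3=("volume_cm3", "max"),
            max_cortical_mm=("cortical_width_mm", "max"),
            palpable_any=("palpable", "max"),
        )
        nd_grades = (
            nodes[nodes["is_nondominant"]]
            .groupby(key, sort=False)
            .agg(
                lnv_nd_grade=("lnv_grade", "max"),
                lncw_nd_grade=("lncw_grade", "max"),
                lnpd_nd_grade=("lnpd_grade", "max"),
            )
        )
        out = (
            out.merge(per_sv, on=key, how="left")
            .merge(index_sum, on=key, how="left")
            .merge(lnpd_sum, on=key, how="left")
            .merge(nd_grades, on=key, how="left")
        )
    else:
        for col in ("n_detected_nodes", "max_volume_cm3", "max_cortical_mm", "palpable_any",
                    "lnv_index", "lncw_index", "lnpd_index",
                    "lnv_nd_grade", "lncw_nd_grade", "lnpd_nd_grade"):
            out[col] = np.nan

    no_nodes = out["n_detected_nodes"].isna() | (out["n_detected_nodes"] == 0)
    out["n_detected_nodes"] = out["n_detected_nodes"].fillna(0).astype(int)
    for col in ("lnv_index", "lncw_index", "lnv_nd_grade", "lncw_nd_grade"):
        out[col] = out[col].fillna(0).astype(int)
    # 0 is reserved for "no detectable node"; nodes present without any PD
    # assessment keep a missing LNPD index
    out.loc[no_nodes, "lnpd_index"] = 0.0
    out["lnpd_nd_grade"] = out["lnpd_nd_grade"].fillna(0.0)
    out["palpable_any"] = np.where(out["palpable_any"].isna(), False, out["palpable_any"]).astype(int)

    group = subjects.set_index("subject_id")["group"]
    out = out.merge(group.rename("group"), left_on="subject_id", right_index=True, how="left")
    return out


def joint_index_table(cohort: CohortTables) -> pd.DataFrame:
    """Per subject-visit 12-joint GS/PD indices, total and per arm."""
    joints = cohort.joints
    if len(joints) == 0:
        return pd.DataFrame(
            columns=["subject_id", "visit_week", "gs12", "pd12", "gs_nd", "pd_nd", "gs_dom", "pd_dom"]
        )
    dominant = cohort.subjects.set_index("subject_id")["dominant_side"]
    j = joints.merge(dominant.rename("dominant_side"), left_on="subject_id", right_index=True, how="left")
    j["arm"] = np.where(j["side"] == j["dominant_side"], "dom", "nd")
    total = j.groupby(["subject_id", "visit_week"])[["gs_grade", "pd_grade"]].sum()
    by_arm = j.groupby(["subject_id", "visit_week", "arm"])[["gs_grade", "pd_grade"]].sum().unstack("arm", fill_value=0)
    out = total.rename(columns={"gs_grade": "gs12", "pd_grade": "pd12"})
    for arm in ("nd", "dom"):
        out[f"gs_{arm}"] = by_arm.get(("gs_grade", arm), 0)
        out[f"pd_{arm}"] = by_arm.get(("pd_grade", arm), 0)
    return out.reset_index()


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------


def spearman_ci(x, y, alpha: float = 0.05) -> dict:
    """Spearman rho with a Fisher-z confidence interval (variance 1.06/(n−3)).

    Incomplete pairs are dropped; fewer than 4 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise AnalysisError(f"need >= 4 complete pairs for a correlation, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        raise AnalysisError("correlation undefined (constant input)")
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:  # perfect monotone association up to rounding
        rho = float(np.sign(rho))
    z_crit = stats.norm.ppf(1 - alpha / 2)
    if abs(rho) >= 1.0:
        lo = hi = rho
    else:
        z = np.arctanh(rho)
        se = np.sqrt(1.06 / (n - 3))
        lo, hi = np.tanh(z - z_crit * se), np.tanh(z + z_crit * se)
    return {
        "rho": rho,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": float(p),
        "n": int(n),
    }


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def conover_friedman_posthoc(data: np.ndarray) -> dict:
    """Friedman test with Conover pairwise post-hoc comparisons.

    ``data`` is an (n subjects × k conditions) matrix of repeated
    measurements. Returns the tie-corrected Friedman chi-square and p, plus
    unadjusted two-sided pairwise p-values keyed by column-index pairs,
    computed from the Conover t statistic on within-block rank sums with
    (n−1)(k−1) degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise AnalysisError("need an (n >= 2) x (k >= 2) matrix of measurements")
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    R = ranks.sum(axis=0)
    A1 = float((ranks**2).sum())
    C1 = n * k * (k + 1) ** 2 / 4.0
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if A1 <= C1 + 1e-12:  # every block completely tied
        return {
            "friedman_chi2": 0.0,
            "friedman_p": 1.0,
            "pairwise_p": {pair: 1.0 for pair in pairs},
            "rank_sums": R.tolist(),
            "n": n,
        }
    T1 = (k - 1) * float(((R - n * (k + 1) / 2.0) ** 2).sum()) / (A1 - C1)
    friedman_p = float(stats.chi2.sf(T1, k - 1))
    df = (n - 1) * (k - 1)
    spread = 1.0 - T1 / (n * (k - 1))
    pairwise = {}
    for i, j in pairs:
        diff = abs(R[i] - R[j])
        if spread <= 0:
            pairwise[(i, j)] = 0.0 if diff > 1e-12 else 1.0
            continue
        denom = np.sqrt(2.0 * n * (A1 - C1) * spread / df)
        t = diff / denom
        pairwise[(i, j)] = float(2.0 * stats.t.sf(t, df))
    return {
        "friedman_chi2": float(T1),
        "friedman_p": friedman_p,
        "pairwise_p": pairwise,
        "rank_sums": R.tolist(),
        "n": n,
    }


def firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth penalized logistic regression (Jeffreys-prior bias reduction).

    Returns ``(coefficients, standard_errors)``. Used as the flagged fallback
    when maximum likelihood separates; the penalty keeps estimates finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = pi * (1.0 - pi)
        info = X.T @ (X * w[:, None])
        info_inv = np.linalg.pinv(info)
        root_w = np.sqrt(w)
        hat = (X * root_w[:, None]) @ info_inv @ (X * root_w[:, None]).T
        h = np.diag(hat)
        score = X.T @ (y - pi + h * (0.5 - pi))
        step = info_inv @ score
        # dampen very large steps for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = pi * (1.0 - pi)
    info_inv = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(info_inv))


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def _median_range(values: np.ndarray) -> tuple[float, float, float]:
    return float(np.median(values)), float(values.min()), float(values.max())


def compare_groups(
    cohort: CohortTables, calibration: CalibrationModel = DEFAULT_CALIBRATION
) -> pd.DataFrame:
    """Baseline RA-vs-control comparisons of LN parameters.

    Ordinal/continuous measures use a two-sided Mann-Whitney test (normal
    approximation with tie correction for larger samples, exact enumeration
    for small tie-free samples); proportions use chi-square with a Fisher
    exact fallback when any expected cell count is below 5.
    """
    idx = subject_ln_indices(cohort, calibration)
    idx = idx[idx["visit_week"] == 0]
    ra = idx[idx["group"] == "RA"]
    control = idx[idx["group"] == "control"]
    if len(ra) == 0 or len(control) == 0:
        raise AnalysisError("both an RA group and a control group are required")

    rows = []
    continuous = [
        ("lnv_index", "lnv_index"),
        ("lncw_index", "lncw_index"),
        ("lnpd_index", "lnpd_index"),
        ("max_volume_cm3", "max LNV (cm3)"),
        ("max_cortical_mm", "max LNCW (mm)"),
        ("n_detected_nodes", "detected LN count"),
    ]
    for col, label in continuous:
        a = ra[col].dropna().to_numpy(dtype=float)
        b = control[col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        med_a, lo_a, hi_a = _median_range(a)
        med_b, lo_b, hi_b = _median_range(b)
        rows.append(
            {
                "measure": label,
                "test": "mann-whitney",
                "statistic": float(stat),
                "p_value": float(p),
                "ra_median": med_a,
                "ra_min": lo_a,
                "ra_max": hi_a,
                "control_median": med_b,
                "control_min": lo_b,
                "control_max": hi_b,
            }
        )

    proportions = [
        ("ln_detected", (idx["n_detected_nodes"] > 0).astype(int)),
        ("palpable_ln", idx["palpable_any"].astype(int)),
    ]
    for label, indicator in proportions:
        tab = pd.crosstab(idx["group"], indicator).reindex(
            index=["RA", "control"], columns=[0, 1], fill_value=0
        )
        table = tab.to_numpy()
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            test, stat = "fisher-exact", float(odds)
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            test, stat = "chi-square", float(chi2)
        rows.append(
            {
                "measure": label,
                "test": test,
                "statistic": stat,
                "p_value": float(p),
                "ra_median": float(table[0, 1] / table[0].sum()),
                "ra_min": np.nan,
                "ra_max": np.nan,
                "control_median": float(table[1, 1] / table[1].sum()),
                "control_min": np.nan,
                "control_max": np.nan,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    cohort: CohortTables, calibration: CalibrationModel = DEFAULT_CALIBRATION
) -> pd.DataFrame:
    """Baseline Spearman panel: LN indices vs serology, joint counts and joint
    US indices, with ipsilateral/contralateral (nondominant-arm) blocks."""
    idx = subject_ln_indices(cohort, calibration)
    idx = idx[(idx["visit_week"] == 0) & (idx["group"] == "RA")]
    if len(idx) == 0:
        raise AnalysisError("no RA baseline visits in cohort")
    joints = joint_index_table(cohort)
    joints = joints[joints["visit_week"] == 0]
    merged = (
        idx.merge(cohort.subjects, on="subject_id", how="left")
        .merge(joints.drop(columns=["visit_week"]), on="subject_id", how="left")
        .merge(
            cohort.visits[cohort.visits["visit_week"] == 0].drop(columns=["visit_week"]),
            on="subject_id",
            how="left",
        )
    )

    has_nd_counts = {"tjc_nondominant", "sjc_nondominant"} <= set(merged.columns)
    rows = []
    for param in ("lnv", "lncw", "lnpd"):
        total_col = f"{param}_index"
        nd_col = f"{param}_nd_grade"
        panel = [
            ("acpa_titer_u_ml", "all", total_col, None),
            ("acpa_titer_u_ml", "seropositive", total_col, merged["acpa_positive"] == 1),
            ("rf_titer_u_ml", "all", total_col, None),
            ("rf_titer_u_ml", "seropositive", total_col, merged["rf_positive"] == 1),
            ("tjc28", "total", total_col, None),
            ("sjc28", "total", total_col, None),
            ("gs12", "total", total_col, None),
            ("gs_nd", "ipsilateral", nd_col, None),
            ("gs_dom", "contralateral", nd_col, None),
            ("pd12", "total", total_col, None),
            ("pd_nd", "ipsilateral", nd_col, None),
            ("pd_dom", "contralateral", nd_col, None),
        ]
        if has_nd_counts:
            panel.insert(5, ("tjc_nondominant", "ipsilateral", nd_col, None))
            panel.insert(7, ("sjc_nondominant", "ipsilateral", nd_col, None))
        for covariate, block, ln_col, mask in panel:
            if covariate not in merged.columns:
                rows.append(
                    {
                        "ln_index": total_col,
                        "covariate": covariate,
                        "block": block,
                        "rho": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "n": 0,
                        "note": "covariate not available",
                    }
                )
                continue
            sub = merged if mask is None else merged[mask]
            try:
                res = spearman_ci(sub[ln_col], sub[covariate])
                note = ""
            except AnalysisError as exc:
                res = {"rho": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "n": 0}
                note = str(exc)
            rows.append(
                {
                    "ln_index": total_col,
                    "covariate": covariate,
                    "block": block,
                    **res,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def _visit_matrix(table: pd.DataFrame, value_col: str, weeks=(0, 4, 24)) -> pd.DataFrame:
    """Subjects × weeks matrix keeping only subjects with all three visits."""
    wide = table.pivot_table(index="subject_id", columns="visit_week", values=value_col, aggfunc="first")
    missing = [w for w in weeks if w not in wide.columns]
    if missing:
        return pd.DataFrame(columns=list(weeks))
    return wide[list(weeks)].dropna()


def signed_rank_exact_p(diff: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value (zeros dropped).

    Enumerates the full sign-flip null distribution of the positive-rank sum
    by dynamic programming over the (tie-averaged) ranks, so the p-value is
    exact and deterministic for any handful-to-dozens sample size:
    p = min(1, 2*min(P(W <= w), P(W >= w))).
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    # doubled ranks are integers even with average ties
    r2 = np.round(2 * ranks).astype(int)
    w2 = int(np.round(2 * ranks[d > 0].sum()))
    # characteristic polynomial of the W+ distribution over doubled ranks
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:  # r >= 2 always (doubled ranks)
        dist[r:] += dist[:-r].copy()
    dist /= 2.0**m
    less = float(dist[: w2 + 1].sum())
    greater = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(less, greater))


def _signed_rank_posthoc(matrix: np.ndarray) -> list[float]:
    """Unadjusted exact signed-rank p-values of each later visit vs baseline."""
    return [signed_rank_exact_p(matrix[:, 0] - matrix[:, j]) for j in range(1, matrix.shape[1])]


def longitudinal_response(
    cohort: CohortTables,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    weeks: tuple = (0, 4, 24),
    posthoc: str = "wilcoxon",
) -> dict:
    """Treatment-course analysis of LN indices and the joint PD index.

    Each LN index is analyzed in the subgroup with a baseline value above the
    control range (the maximum observed among controls); the joint PD index
    in the subgroup with baseline pd12 > 0. Friedman chi-square across the
    three visits, then post-hoc pairwise comparisons of weeks 4 and 24
    against baseline under Holm multiplicity control.

    ``posthoc`` selects the pairwise test: ``"wilcoxon"`` (exact signed-rank;
    the default, because its per-comparison size stays calibrated when one
    visit carries a strong effect) or ``"conover"`` (rank-sum comparisons
    with the variance pooled across all visits, which borrows strength from
    the Friedman statistic but becomes liberal for the unaffected visit when
    another visit moves far).
    """
    idx = subject_ln_indices(cohort, calibration)
    controls = idx[(idx["group"] == "control") & (idx["visit_week"] == 0)]
    ra = idx[idx["group"] == "RA"]
    joints = joint_index_table(cohort)

    out = {}
    specs = []
    for param in ("lnv_index", "lncw_index", "lnpd_index"):
        threshold = float(controls[param].max()) if len(controls) else 0.0
        specs.append((param, ra, param, threshold))
    specs.append(("pd12_index", joints, "pd12", 0.0))

    for name, table, col, threshold in specs:
        wide = _visit_matrix(table, col, weeks)
        n_all = len(wide)
        wide = wide[wide[weeks[0]] > threshold]
        entry = {
            "threshold": threshold,
            "n": int(len(wide)),
            "n_complete_visits": int(n_all),
            "medians": {int(w): (float(wide[w].median()) if len(wide) else np.nan) for w in weeks},
        }
        if len(wide) < 3:
            entry.update(
                {
                    "friedman_chi2": np.nan,
                    "friedman_p": np.nan,
                    "posthoc_p": {},
                    "note": "fewer than 3 subjects above threshold with complete visits",
                }
            )
            out[name] = entry
            continue
        res = conover_friedman_posthoc(wide.to_numpy())
        if posthoc == "wilcoxon":
            raw = _signed_rank_posthoc(wide.to_numpy())
        elif posthoc == "conover":
            raw = [res["pairwise_p"][(0, 1)], res["pairwise_p"][(0, 2)]]
        else:
            raise AnalysisError(f"unknown posthoc method {posthoc!r}")
        adj = holm_adjust(raw)
        entry.update(
            {
                "friedman_chi2": res["friedman_chi2"],
                "friedman_p": res["friedman_p"],
                "posthoc_p": {int(weeks[1]): adj[0], int(weeks[2]): adj[1]},
                "note": "",
            }
        )
        out[name] = entry
    return out


def _das28_by_visit(cohort: CohortTables) -> pd.DataFrame:
    v = cohort.visits.copy()
    if "das28" in v.columns and v["das28"].notna().all():
        v["das28_value"] = v["das28"].astype(float)
    else:
        v["das28_value"] = das28_esr(
            v["tjc28"].to_numpy(float),
            v["sjc28"].to_numpy(float),
            v["esr_mm_h"].to_numpy(float),
            v["vas_ptga_mm"].to_numpy(float),
        )
    return v[["subject_id", "visit_week", "das28_value"]]


def external_responsiveness(
    cohort: CohortTables, calibration: CalibrationModel = DEFAULT_CALIBRATION
) -> pd.DataFrame:
    """OLS of LN index change on ipsilateral joint PD change and DAS28 change.

    Change scores are baseline − follow-up (positive = reduction), computed
    at weeks 4 and 24 separately. Reports R², the regression p-value and the
    slope; a zero-variance regressor is reported as an undefined fit.
    """
    idx = subject_ln_indices(cohort, calibration)
    ra = idx[idx["group"] == "RA"]
    joints = joint_index_table(cohort)
    das = _das28_by_visit(cohort)

    rows = []
    for week in (4, 24):
        for param in ("lnpd_index", "lnv_index", "lncw_index"):
            wide = _visit_matrix(ra, param, (0, week))
            if len(wide) == 0:
                continue
            delta_ln = wide[0] - wide[week]
            regressors = {
                "delta_pd_ipsilateral": _visit_matrix(joints, "pd_nd", (0, week)),
                "delta_das28": _visit_matrix(das, "das28_value", (0, week)),
            }
            for reg_name, reg_wide in regressors.items():
                joined = pd.concat(
                    [delta_ln.rename("y"), (reg_wide[0] - reg_wide[week]).rename("x")],
                    axis=1,
                ).dropna()
                row = {
                    "week": week,
                    "ln_index": param,
                    "regressor": reg_name,
                    "n": int(len(joined)),
                }
                if len(joined) < 4 or np.isclose(joined["x"].var(), 0) or np.isclose(joined["y"].var(), 0):
                    row.update({"r2": np.nan, "p_value": np.nan, "slope": np.nan, "note": "undefined fit (too few pairs or zero variance)"})
                else:
                    fit = sm.OLS(joined["y"], sm.add_constant(joined["x"])).fit()
                    row.update(
                        {
                            "r2": float(fit.rsquared),
                            "p_value": float(fit.f_pvalue),
                            "slope": float(fit.params["x"]),
                            "note": "",
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _response_labels(cohort: CohortTables, followup_week: int = 24) -> pd.DataFrame:
    das = _das28_by_visit(cohort)
    wide = _visit_matrix(das, "das28_value", (0, followup_week))
    labels = []
    for sid, row in wide.iterrows():
        lab = eular_response(row[0], row[followup_week])
        labels.append(
            {
                "subject_id": sid,
                "das28_baseline": float(row[0]),
                "good_response": int(lab.category == "good"),
                "category": lab.category,
                "remission": int(lab.remission),
            }
        )
    return pd.DataFrame(labels)


def predict_response(
    cohort: CohortTables,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    models: Sequence[str] = ("model1", "model2"),
    followup_week: int = 24,
) -> dict:
    """Logistic prediction of good EULAR response from baseline LNPD = 0.

    Model 1 adjusts for the baseline 12-joint PD index; model 2 additionally
    for age, sex, disease duration, glucocorticoid co-medication and baseline
    DAS28. Reports the odds ratio for the [baseline LNPD index = 0]
    indicator with Wald 95 % CI and p. Complete separation (or a divergent
    ML fit) is flagged and handled by a Firth penalized fit.
    """
    labels = _response_labels(cohort, followup_week)
    if len(labels) < 10:
        raise AnalysisError(
            f"need >= 10 subjects with outcome labels, got {len(labels)}"
        )
    idx = subject_ln_indices(cohort, calibration)
    base = idx[(idx["visit_week"] == 0)][["subject_id", "lnpd_index"]]
    joints = joint_index_table(cohort)
    pd12 = joints[joints["visit_week"] == 0][["subject_id", "pd12"]]
    data = (
        labels.merge(base, on="subject_id", how="left")
        .merge(pd12, on="subject_id", how="left")
        .merge(cohort.subjects, on="subject_id", how="left")
    )
    data["lnpd0"] = (data["lnpd_index"] == 0).astype(float)
    data["female"] = (data["sex"] == "F").astype(float)
    data["gc"] = data["on_glucocorticoids"].astype(float)

    covariates = {
        "model1": ["pd12"],
        "model2": ["pd12", "age_years", "female", "disease_duration_months", "gc", "das28_baseline"],
    }
    out = {}
    for model in models:
        cols = ["lnpd0"] + covariates[model]
        sub = data[["good_response"] + cols].dropna()
        y = sub["good_response"].to_numpy(dtype=float)
        X = sm.add_constant(sub[cols].to_numpy(dtype=float))
        separation = False
        beta = bse = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, bse = np.asarray(fit.params), np.asarray(fit.bse)
            if (not fit.mle_retvals.get("converged", False)) or np.any(np.abs(beta) > 12) or np.any(bse > 50) or not np.all(np.isfinite(bse)):
                separation = True
        except Exception:
            separation = True
        method = "mle"
        if separation:
            beta, bse = firth_logit(X, y)
            method = "firth"
        k = 1  # position of the lnpd0 coefficient (after the constant)
        or_hat = float(np.exp(beta[k]))
        z = stats.norm.ppf(0.975)
        ci = (float(np.exp(beta[k] - z * bse[k])), float(np.exp(beta[k] + z * bse[k])))
        wald = beta[k] / bse[k] if bse[k] > 0 else np.nan
        out[model] = {
            "odds_ratio": or_hat,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": float(2 * stats.norm.sf(abs(wald))) if np.isfinite(wald) else np.nan,
            "n": int(len(sub)),
            "n_good": int(sub["good_response"].sum()),
            "method": method,
            "separation": bool(separation),
            "covariates": covariates[model],
        }
    return out


def analyze_cohort(
    cohort: CohortTables,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    baseline_only: bool = False,
) -> dict:
    """Run the full analysis battery; returns a JSON-serializable report."""
    report: Dict[str, object] = {
        "n_subjects": int(len(cohort.subjects)),
        "n_ra": int((cohort.subjects["group"] == "RA").sum()),
        "n_controls": int((cohort.subjects["group"] == "control").sum()),
        "calibration": {
            "uln_volume_cm3": calibration.uln_volume_cm3,
            "uln_cortical_mm": calibration.uln_cortical_mm,
            "lncw_step_mm": calibration.lncw_step_mm,
            "pd_count_bins": list(calibration.pd_count_bins),
        },
        "group_comparisons": compare_groups(cohort, calibration).to_dict(orient="records"),
        "correlation_table": correlation_table(cohort, calibration).to_dict(orient="records"),
    }
    if not baseline_only:
        has_followup = cohort.visits["visit_week"].nunique() >= 3 if len(cohort.visits) else False
        if has_followup:
            longitudinal = longitudinal_response(cohort, calibration)
            report["longitudinal"] = {
                name: {
                    **{k: v for k, v in entry.items() if k != "posthoc_p"},
                    "posthoc_p": {str(k): v for k, v in entry["posthoc_p"].items()},
                    "medians": {str(k): v for k, v in entry["medians"].items()},
                }
                for name, entry in longitudinal.items()
            }
            report["responsiveness"] = external_responsiveness(cohort, calibration).to_dict(orient="records")
            try:
                report["prediction"] = predict_response(cohort, calibration)
            except AnalysisError as exc:
                report["prediction"] = {"note": str(exc)}
    return report
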