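"""Statistics pipeline: primitives against oracles, and crafted-cohort checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nodax.grading import LymphNodeRecord, cumulative_index
from nodax.stats import (
    AnalysisError,
    analyze_cohort,
    compare_groups,
    conover_friedman_posthoc,
    correlation_table,
    external_responsiveness,
    firth_logit,
    holm_adjust,
    joint_index_table,
    longitudinal_response,
    predict_response,
    spearman_ci,
    subject_ln_indices,
)
from nodax.tables import CohortTables

# ---------------------------------------------------------------------------
# crafted cohorts
# ---------------------------------------------------------------------------

#: PD signal counts that land exactly in each grade band
COUNT_FOR_GRADE = {0: 0, 1: 2, 2: 4, 3: 6}


def build_cohort(ra_specs, control_specs=()):
    """Assemble CohortTables from per-subject dictionaries.

    Each spec may carry ``nodes``: {week: [(side, volume_like, cw, count)]},
    ``joints``: {week: [(side, joint_id, gs, pd)]}, ``das``: {week: value}.
    Volumes are specified directly and converted to a sphere's axes.
    """
    subjects, nodes, joints, visits = [], [], [], []
    for group, specs in (("RA", ra_specs), ("control", control_specs)):
        for spec in specs:
            sid = spec["id"]
            subjects.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age_years": spec.get("age", 55.0),
                    "sex": spec.get("sex", "F"),
                    "dominant_side": spec.get("dominant", "right"),
                    "disease_duration_months": spec.get("duration", 24.0),
                    "rf_positive": 1,
                    "rf_titer_u_ml": spec.get("rf", 50.0),
                    "acpa_positive": 1,
                    "acpa_titer_u_ml": spec.get("acpa", 60.0),
                    "on_glucocorticoids": spec.get("gc", 0),
                }
            )
            for week, node_list in spec.get("nodes", {}).items():
                for side, volume, cw, count in node_list:
                    diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)
                    nodes.append(
                        {
                            "subject_id": sid,
                            "visit_week": week,
                            "side": side,
                            "long_axis_cm": diameter,
                            "short_axis_cm": diameter,
                            "cortical_width_mm": cw,
                            "pd_cortical_signal_count": count,
                            "palpable": 0,
                        }
                    )
            for week, joint_list in spec.get("joints", {}).items():
                for side, jid, gs, pd_grade in joint_list:
                    joints.append(
                        {
                            "subject_id": sid,
                            "visit_week": week,
                            "side": side,
                            "joint_id": jid,
                            "gs_grade": gs,
                            "pd_grade": pd_grade,
                        }
                    )
            for week, das in spec.get("das", {}).items():
                visits.append(
                    {
                        "subject_id": sid,
                        "visit_week": week,
                        "tjc28": spec.get("tjc", 6),
                        "sjc28": spec.get("sjc", 3),
                        "esr_mm_h": 20.0,
                        "vas_ptga_mm": 50,
                        "das28": das,
                    }
                )
    cols = dict(
        subjects=subjects, lymph_nodes=nodes, joints=joints, visits=visits
    )
    frames = {k: pd.DataFrame(v) for k, v in cols.items()}
    if not len(frames["visits"]):
        frames["visits"] = pd.DataFrame(
            columns=["subject_id", "visit_week", "tjc28", "sjc28", "esr_mm_h", "vas_ptga_mm", "das28"]
        )
    return CohortTables(**frames)


# ---------------------------------------------------------------------------
# primitives vs oracles
# ---------------------------------------------------------------------------


class TestRankTestOracles:
    def test_mann_whitney_matches_exhaustive_permutation(self, rng):
        """Exact two-sided p equals enumeration over all group assignments."""
        for _ in range(5):
            n1, n2 = int(rng.integers(3, 5)), int(rng.integers(3, 5))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free ranks
            a, b = pooled[:n1], pooled[n1:]
            u_obs = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
            # enumerate the U distribution
            us = []
            for combo in itertools.combinations(range(n1 + n2), n1):
                ga = pooled[list(combo)]
                gb = np.delete(pooled, list(combo))
                us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
            us = np.asarray(us)
            mean_u = n1 * n2 / 2
            p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)
            p_ours = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p_ours == pytest.approx(p_exact, abs=1e-9)

    def test_spearman_matches_rank_pearson(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho = spearman_ci(x, y)["rho"]
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)


class TestSpearmanCI:
    def test_monotone_transform_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        res = spearman_ci(x, np.exp(x))
        assert res["rho"] == pytest.approx(1.0)
        assert res["ci_low"] == res["ci_high"] == 1.0

    def test_ci_contains_point_estimate(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_ci(x, y)
        assert res["ci_low"] <= res["rho"] <= res["ci_high"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(AnalysisError):
            spearman_ci([1, 2, 3], [3, 2, 1])

    def test_nan_pairs_dropped(self):
        x = [1, 2, 3, 4, np.nan]
        y = [1, 2, 3, 4, 5]
        assert spearman_ci(x, y)["n"] == 4

    def test_null_coverage_near_95pct(self):
        """Fisher-z interval covers rho=0 in about 95% of null replicates."""
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=40), rng.normal(size=40)
            res = spearman_ci(x, y)
            covered += res["ci_low"] <= 0.0 <= res["ci_high"]
        assert 0.93 <= covered / reps <= 0.97


class TestHolm:
    def test_two_hypotheses(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_three_hypotheses_with_monotonicity(self):
        assert holm_adjust([0.03, 0.01, 0.04]) == pytest.approx([0.06, 0.03, 0.06])

    def test_order_equivariance(self, rng):
        p = rng.uniform(size=6)
        perm = rng.permutation(6)
        adjusted = np.asarray(holm_adjust(p))
        assert np.allclose(np.asarray(holm_adjust(p[perm])), adjusted[perm])


class TestFriedmanPosthoc:
    def test_tie_free_statistic_matches_scipy(self, rng):
        for _ in range(10):
            data = rng.normal(size=(8, 3))
            ours = conover_friedman_posthoc(data)
            chi2, p = sps.friedmanchisquare(*data.T)
            assert ours["friedman_chi2"] == pytest.approx(chi2, rel=1e-9)
            assert ours["friedman_p"] == pytest.approx(p, rel=1e-9)

    def test_fully_tied_blocks(self):
        data = np.ones((6, 3))
        res = conover_friedman_posthoc(data)
        assert res["friedman_p"] == 1.0
        assert all(p == 1.0 for p in res["pairwise_p"].values())

    def test_consistent_ordering_detected(self):
        data = np.tile([3.0, 2.0, 1.0], (10, 1)) + np.linspace(0, 0.1, 10)[:, None]
        res = conover_friedman_posthoc(data)
        assert res["friedman_p"] < 1e-3
        assert res["pairwise_p"][(0, 2)] < 0.01

    def test_bad_shape_rejected(self):
        with pytest.raises(AnalysisError):
            conover_friedman_posthoc(np.ones((1, 3)))


class TestFirthLogit:
    def test_finite_under_complete_separation(self):
        x = np.array([0.0] * 6 + [1.0] * 6)
        y = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([np.ones_like(x), x])
        beta, bse = firth_logit(X, y)
        assert np.all(np.isfinite(beta)) and np.all(np.isfinite(bse))
        assert beta[1] > 0

    def test_agrees_with_mle_when_well_conditioned(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=3000)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(3000) < p).astype(float)
        X = sm.add_constant(x)
        mle = sm.Logit(y, X).fit(disp=0)
        beta, _ = firth_logit(X, y)
        assert beta == pytest.approx(np.asarray(mle.params), abs=0.02)


# ---------------------------------------------------------------------------
# derived tables against the record-level implementation
# ---------------------------------------------------------------------------


class TestDerivedTables:
    def test_subject_indices_match_record_level_path(self, default_cohort):
        """Dual route: vectorized table vs per-record cumulative_index."""
        table = subject_ln_indices(default_cohort).set_index(["subject_id", "visit_week"])
        nodes = default_cohort.lymph_nodes
        checked = 0
        for (sid, week), group in nodes.groupby(["subject_id", "visit_week"]):
            records = [
                LymphNodeRecord(
                    sid, int(week), r.side, r.long_axis_cm, r.short_axis_cm,
                    r.cortical_width_mm, int(r.pd_cortical_signal_count), bool(r.palpable),
                )
                for r in group.itertuples()
            ]
            expected = cumulative_index(records)
            got = table.loc[(sid, week)]
            assert got["lnv_index"] == expected.lnv_index
            assert got["lncw_index"] == expected.lncw_index
            assert got["lnpd_index"] == expected.lnpd_index
            assert got["n_detected_nodes"] == expected.n_detected_nodes
            checked += 1
            if checked >= 40:
                break
        assert checked >= 20

    def test_subjects_without_nodes_score_zero(self, default_cohort):
        table = subject_ln_indices(default_cohort)
        empty = table[table["n_detected_nodes"] == 0]
        assert (empty[["lnv_index", "lncw_index", "lnpd_index"]] == 0).all().all()

    def test_joint_table_matches_manual_sums(self, default_cohort):
        table = joint_index_table(default_cohort).set_index(["subject_id", "visit_week"])
        joints = default_cohort.joints
        sample = joints.groupby(["subject_id", "visit_week"]).sum(numeric_only=True)
        for key in list(sample.index)[:25]:
            sub = joints[(joints.subject_id == key[0]) & (joints.visit_week == key[1])]
            assert table.loc[key, "pd12"] == sub["pd_grade"].sum()
            assert table.loc[key, "gs12"] == sub["gs_grade"].sum()
            row = table.loc[key]
            assert row["pd12"] == row["pd_nd"] + row["pd_dom"]


# ---------------------------------------------------------------------------
# pipeline operations on crafted cohorts
# ---------------------------------------------------------------------------


def _identical_groups_cohort():
    volumes = [0.15, 0.2, 0.3, 0.4, 0.5, 0.25]
    ra = [
        {"id": f"R{i}", "nodes": {0: [("right", v, 2.5, 1)]}, "das": {0: 5.0}}
        for i, v in enumerate(volumes)
    ]
    control = [
        {"id": f"C{i}", "nodes": {0: [("right", v, 2.5, 1)]}}
        for i, v in enumerate(volumes)
    ]
    return build_cohort(ra, control)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups(_identical_groups_cohort()).set_index("measure")
        assert res.loc["max LNV (cm3)", "p_value"] > 0.8
        assert res.loc["max LNV (cm3)", "ra_median"] == res.loc["max LNV (cm3)", "control_median"]

    def test_clear_shift_detected(self):
        ra = [
            {"id": f"R{i}", "nodes": {0: [("right", 1.5 + 0.1 * i, 6.0, 7)]}, "das": {0: 5.0}}
            for i in range(8)
        ]
        control = [
            {"id": f"C{i}", "nodes": {0: [("right", 0.15 + 0.01 * i, 2.0, 0)]}}
            for i in range(8)
        ]
        res = compare_groups(build_cohort(ra, control)).set_index("measure")
        assert res.loc["lnv_index", "p_value"] < 0.01
        assert res.loc["lnv_index", "ra_median"] > res.loc["lnv_index", "control_median"]

    def test_missing_group_rejected(self):
        cohort = build_cohort([{"id": "R1", "nodes": {0: [("right", 0.2, 2.0, 0)]}, "das": {0: 5.0}}])
        with pytest.raises(AnalysisError):
            compare_groups(cohort)

    def test_row_order_invariance(self, default_cohort, rng):
        shuffled = CohortTables(
            subjects=default_cohort.subjects.sample(frac=1, random_state=1).reset_index(drop=True),
            lymph_nodes=default_cohort.lymph_nodes.sample(frac=1, random_state=2).reset_index(drop=True),
            joints=default_cohort.joints.sample(frac=1, random_state=3).reset_index(drop=True),
            visits=default_cohort.visits.sample(frac=1, random_state=4).reset_index(drop=True),
        )
        a = compare_groups(default_cohort).set_index("measure")["p_value"]
        b = compare_groups(shuffled).set_index("measure")["p_value"]
        assert np.allclose(a.sort_index(), b.sort_index())


class TestCorrelationTable:
    def test_self_monotone_correlation_is_unity(self):
        # LN index against a covariate that is a monotone transform of itself
        ra = [
            {
                "id": f"R{i}",
                "nodes": {0: [("left", 0.3 + 0.35 * i, 2.0, 0)]},
                "das": {0: 5.0},
                "joints": {0: [("left", "wrist", 0, min(3, i)), ("right", "wrist", 0, 0)]},
            }
            for i in range(6)
        ]
        cohort = build_cohort(ra)
        table = correlation_table(cohort)
        row = table[(table.ln_index == "lnv_index") & (table.covariate == "pd_nd")].iloc[0]
        # lnv nd grade and nd joint pd both increase strictly with i (until caps)
        assert row["rho"] > 0.9

    def test_structure_and_blocks(self, default_cohort):
        table = correlation_table(default_cohort)
        assert set(table["block"]) == {"all", "seropositive", "total", "ipsilateral", "contralateral"}
        done = table[table["note"] == ""]
        assert ((done["ci_low"] <= done["rho"]) & (done["rho"] <= done["ci_high"])).all()
        assert (done["n"] >= 4).all()

    def test_short_pairs_skipped_with_reason(self):
        ra = [{"id": f"R{i}", "nodes": {0: [("left", 0.2, 2.0, 0)]}, "das": {0: 5.0}} for i in range(3)]
        table = correlation_table(build_cohort(ra))
        assert (table["note"] != "").all()


class TestLongitudinal:
    def _three_visit_cohort(self, week4_counts, week24_counts, n=10):
        ra = []
        for i in range(n):
            ra.append(
                {
                    "id": f"R{i}",
                    "nodes": {
                        0: [("left", 0.2, 2.0, COUNT_FOR_GRADE[3])],
                        4: [("left", 0.2, 2.0, week4_counts[i])],
                        24: [("left", 0.2, 2.0, week24_counts[i])],
                    },
                    "das": {0: 5.0, 4: 4.5, 24: 4.0},
                }
            )
        control = [{"id": "C1", "nodes": {0: [("left", 0.2, 2.0, 0)]}}]
        return build_cohort(ra, control)

    def test_no_change_gives_null_result(self):
        c6 = [COUNT_FOR_GRADE[3]] * 10
        res = longitudinal_response(self._three_visit_cohort(c6, c6))["lnpd_index"]
        assert res["friedman_p"] == pytest.approx(1.0)
        assert all(p == 1.0 for p in res["posthoc_p"].values())

    def test_strict_decrease_at_both_visits(self):
        w4 = [COUNT_FOR_GRADE[2]] * 10
        w24 = [COUNT_FOR_GRADE[0]] * 10
        res = longitudinal_response(self._three_visit_cohort(w4, w24))["lnpd_index"]
        assert res["friedman_p"] < 0.001
        assert res["posthoc_p"][4] < 0.05
        assert res["posthoc_p"][24] < 0.05

    def test_week24_only_decrease(self):
        w4 = [COUNT_FOR_GRADE[3]] * 10
        w24 = [COUNT_FOR_GRADE[0]] * 10
        res = longitudinal_response(self._three_visit_cohort(w4, w24))["lnpd_index"]
        assert res["posthoc_p"][24] < 0.05
        assert res["posthoc_p"][4] > 0.5

    def test_conover_variant_runs(self):
        w4 = [COUNT_FOR_GRADE[2]] * 10
        w24 = [COUNT_FOR_GRADE[0]] * 10
        res = longitudinal_response(self._three_visit_cohort(w4, w24), posthoc="conover")["lnpd_index"]
        assert res["posthoc_p"][24] < 0.05

    def test_small_subgroup_reported_not_crashed(self):
        c6 = [COUNT_FOR_GRADE[3]] * 2
        cohort = self._three_visit_cohort(c6, c6, n=2)
        res = longitudinal_response(cohort)["lnpd_index"]
        assert res["note"]
        assert np.isnan(res["friedman_p"])


class TestResponsiveness:
    def _coupled_cohort(self):
        """Week-24 LN change exactly equals the ipsilateral joint PD change."""
        deltas = [3, 2, 0, 1, 3, 0, 2, 1]
        ra = []
        for i, d in enumerate(deltas):
            ra.append(
                {
                    "id": f"R{i}",
                    "nodes": {
                        0: [("left", 0.2, 2.0, COUNT_FOR_GRADE[3])],
                        4: [("left", 0.2, 2.0, COUNT_FOR_GRADE[3])],
                        24: [("left", 0.2, 2.0, COUNT_FOR_GRADE[3 - d])],
                    },
                    "joints": {
                        0: [("left", "wrist", 0, d)],
                        4: [("left", "wrist", 0, d)],
                        24: [("left", "wrist", 0, 0)],
                    },
                    "das": {0: 5.0, 4: 5.0, 24: 4.0},
                }
            )
        return build_cohort(ra)

    def test_exact_proportionality_gives_r2_one(self):
        table = external_responsiveness(self._coupled_cohort())
        row = table[
            (table.week == 24) & (table.ln_index == "lnpd_index") & (table.regressor == "delta_pd_ipsilateral")
        ].iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)

    def test_zero_variance_regressor_reported_undefined(self):
        table = external_responsiveness(self._coupled_cohort())
        row = table[
            (table.week == 4) & (table.ln_index == "lnpd_index") & (table.regressor == "delta_pd_ipsilateral")
        ].iloc[0]
        assert row["note"]
        assert np.isnan(row["r2"])

    def test_r2_in_unit_interval(self, default_cohort):
        table = external_responsiveness(default_cohort)
        fitted = table[table["note"] == ""]
        assert ((fitted["r2"] >= 0) & (fitted["r2"] <= 1)).all()


class TestPrediction:
    def _separated_cohort(self):
        """LNPD0 perfectly predicts failure: complete separation by design."""
        ra = []
        pd_grades = [0, 1, 2, 3, 1, 2, 0, 3, 1, 2, 3, 1]
        for i in range(12):
            lnpd0 = i < 6
            count = 0 if lnpd0 else COUNT_FOR_GRADE[3]
            das24 = 4.9 if lnpd0 else 2.8  # none vs good response
            ra.append(
                {
                    "id": f"R{i:02d}",
                    "nodes": {0: [("left", 0.2, 2.0, count)]},
                    "joints": {0: [("left", "wrist", 0, pd_grades[i])]},
                    "das": {0: 5.2, 4: 5.0, 24: das24},
                }
            )
        return build_cohort(ra)

    def test_complete_separation_flagged_with_penalized_fallback(self):
        res = predict_response(self._separated_cohort(), models=("model1",))["model1"]
        assert res["separation"]
        assert res["method"] == "firth"
        assert res["odds_ratio"] < 1
        assert np.isfinite(res["ci_low"]) and np.isfinite(res["ci_high"])

    def test_generator_cohort_recovers_negative_association(self, default_cohort):
        res = predict_response(default_cohort)
        for model in ("model1", "model2"):
            assert res[model]["odds_ratio"] < 1
            assert res[model]["ci_low"] <= res[model]["odds_ratio"] <= res[model]["ci_high"]
        assert res["model2"]["covariates"][-1] == "das28_baseline"

    def test_too_few_labels_rejected(self):
        ra = [
            {"id": f"R{i}", "nodes": {0: [("left", 0.2, 2.0, 0)]}, "das": {0: 5.0, 24: 4.0}}
            for i in range(5)
        ]
        with pytest.raises(AnalysisError):
            predict_response(build_cohort(ra))


class TestAnalyzeCohort:
    def test_full_report_structure(self, default_cohort):
        report = analyze_cohort(default_cohort)
        assert {"group_comparisons", "correlation_table", "longitudinal", "responsiveness", "prediction"} <= set(report)
        assert report["n_ra"] == 40 and report["n_controls"] == 20

    def test_baseline_only_skips_longitudinal(self, default_cohort):
        report = analyze_cohort(default_cohort, baseline_only=True)
        assert "longitudinal" not in report and "prediction" not in report
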