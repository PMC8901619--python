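"""Statistical layer: eligibility, tests against enumeration/closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from octavasc.exceptions import CollinearityError, InsufficientDataError
from octavasc.records import ParticipantRecord
from octavasc.stats import (
    ANALYSIS_METRICS,
    TABLE1_LABELS,
    analysis_frame,
    apply_eligibility,
    average_eyes,
    build_reports,
    fit_regression,
    greedy_age_match,
    mann_whitney,
    roc_analysis,
)
from octavasc.synthetic import CohortParams, generate_cohort, make_screening_roster


class TestEligibility:
    def test_printed_screening_counts(self):
        included, report = apply_eligibility(make_screening_roster(seed=0))
        assert report.n_total == 62
        assert report.n_included == len(included) == 30
        assert report.counts_by_reason == {
            "ocular_disease": 18, "poor_image_quality": 9, "neurologic_abnormality": 5,
        }

    def test_no_flags_all_included(self, study_cohort):
        included, report = apply_eligibility(study_cohort)
        assert len(included) == len(study_cohort) and report.n_excluded == 0

    def test_overlapping_flags_counted_once_in_total(self):
        rec = ParticipantRecord(id="X", age=60, sex="f", fazekas=1,
                                exclusion_flags={"ocular_disease", "poor_image_quality"})
        included, report = apply_eligibility([rec])
        assert report.n_excluded == 1
        assert report.counts_by_reason["ocular_disease"] == 1
        assert report.counts_by_reason["poor_image_quality"] == 1
        assert report.n_overlapping == 1


class TestAverageEyes:
    @staticmethod
    def _record(od, os_, q=(10, 10)):
        return ParticipantRecord(
            id="A", age=60, sex="f", fazekas=0,
            eyes={"OD": {"vd_sup": od}, "OS": {"vd_sup": os_}},
            eye_quality={"OD": q[0], "OS": q[1]},
        )

    def test_two_eye_mean(self):
        assert average_eyes(self._record(0.27, 0.29))["vd_sup"] == pytest.approx(0.28)

    def test_single_eligible_eye_is_identity(self):
        out = average_eyes(self._record(0.27, 0.29, q=(10, 5)))
        assert out["vd_sup"] == 0.27

    def test_permutation_invariance(self):
        a = average_eyes(self._record(0.2, 0.3))
        b = average_eyes(self._record(0.3, 0.2))
        assert a == b

    def test_no_eligible_eye_raises(self):
        with pytest.raises(InsufficientDataError):
            average_eyes(self._record(0.2, 0.3, q=(5, 5)))


class TestMannWhitney:
    def test_exact_small_sample_by_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney(a, b)
        assert res.U == 0.0 and res.method == "exact"
        # enumeration oracle over all C(6,3) = 20 assignments of ranks to group a
        combined = np.array(a + b)
        observed = res.U
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            ranks = sps.rankdata(combined)[list(idx)]
            u = ranks.sum() - 3 * 4 / 2
            u_two = min(u, 9 - u)
            total += 1
            count += u_two <= min(observed, 9 - observed)
        assert res.p == pytest.approx(count / total)  # = 2/20 = 0.1
        assert res.p == pytest.approx(0.1)

    def test_full_ties_give_null_statistic(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.U == 3 * 2 / 2
        assert res.p == 1.0

    def test_asymptotic_matches_reference_implementation(self, rng):
        for _ in range(10):
            a = np.round(rng.normal(0, 1, 30), 1)  # rounding creates ties
            b = np.round(rng.normal(0.3, 1, 15), 1)
            mine = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])

    def test_type_i_error_near_nominal_under_null(self, rng):
        reps, rejections = 1000, 0
        for _ in range(reps):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 10)
            rejections += mann_whitney(a, b).p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_identical_scores(self):
        res = roc_analysis([5.0] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        assert res.auc == 0.5

    def test_pair_counting_oracle(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = np.array([1] * 20 + [0] * 10)
        res = roc_analysis(scores, labels, direction="case_high")
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(conc / (20 * 10))

    def test_negation_complements_auc(self, rng):
        scores = rng.normal(0, 1, 24)  # continuous: tie-free
        labels = rng.integers(0, 2, 24)
        labels[:2] = [0, 1]
        a1 = roc_analysis(scores, labels, direction="case_high").auc
        a2 = roc_analysis(-scores, labels, direction="case_high").auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_p_equals_mann_whitney_p(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = np.array([1] * 18 + [0] * 12)
        res = roc_analysis(scores, labels)
        mw = mann_whitney(scores[labels == 1], scores[labels == 0])
        assert res.p == mw.p

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(0.5, 1, 30)
        labels = np.array([1] * 20 + [0] * 10)
        res = roc_analysis(scores, labels)
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestRegression:
    def test_exact_linear_interpolation(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"y": 2 - 5 * x, "x": x})
        res = fit_regression(df, "y", "x")
        est = res.coefficients["x"]
        assert est.beta == pytest.approx(-5.0, abs=1e-8)
        assert est.ci95[1] - est.ci95[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        df = pd.DataFrame({
            "y": rng.normal(0, 1, n), "x": rng.normal(0, 1, n), "age": rng.normal(60, 8, n),
        })
        res = fit_regression(df, "y", "x", covariates=("age",))
        X = np.column_stack([np.ones(n), df["x"], df["age"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res.coefficients["x"].beta == pytest.approx(beta[1], abs=1e-8)
        assert res.coefficients["age"].beta == pytest.approx(beta[2], abs=1e-8)

    def test_collinear_pair_named(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"y": rng.normal(0, 1, 30), "x": x, "x2": 2 * x})
        with pytest.raises(CollinearityError, match=r"\(x, x2\)"):
            fit_regression(df, "y", "x", covariates=("x2",))

    def test_scale_equivariance(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 40), "x": rng.normal(0, 2, 40)})
        b = fit_regression(df, "y", "x").coefficients["x"].beta
        df2 = df.assign(x=df.x / df.x.std())
        b2 = fit_regression(df2, "y", "x").coefficients["x"].beta
        assert b2 == pytest.approx(b * df.x.std())

    def test_age_adjustment_deconfounds_structural_slope(self):
        params = CohortParams(n_cases=5000, n_controls=2,
                              include_flow_voids=False, rng_seed=11)
        df, _ = analysis_frame(generate_cohort(params))
        cases = df[df.group == "case"]
        unadj = fit_regression(cases, "nol", "vd_deep").coefficients["vd_deep"].beta
        adj = fit_regression(cases, "nol", "vd_deep",
                             covariates=("age",)).coefficients["vd_deep"].beta
        assert adj == pytest.approx(-200.0, rel=0.10)
        assert abs(unadj - (-200.0)) > abs(adj - (-200.0))  # confounding bias removed


class TestReports:
    def test_schema_contains_every_table1_row(self, study_cohort):
        report = build_reports(study_cohort)
        assert set(report.table1["parameter"]) == set(TABLE1_LABELS.values())
        for col in ("cases_mean", "controls_mean", "p_all", "p_matched"):
            assert col in report.table1.columns
        assert set(report.roc["metric"]) <= set(ANALYSIS_METRICS)

    def test_cases_only_regressions_use_cases(self, study_cohort):
        report = build_reports(study_cohort)
        n_cases = sum(r.group == "case" for r in study_cohort)
        assert (report.table3["n"] <= n_cases).all()
        assert (report.table3["sample"] == "cases_only").all()

    def test_greedy_matching_reduces_age_gap(self):
        improved = 0
        for seed in range(20):
            df, _ = analysis_frame(generate_cohort(
                CohortParams(include_flow_voids=False, rng_seed=100 + seed)))
            cases, controls = greedy_age_match(df)
            full_gap = abs(df[df.group == "case"].age.mean()
                           - df[df.group == "control"].age.mean())
            matched_gap = abs(df[df.id.isin(cases)].age.mean()
                              - df[df.id.isin(controls)].age.mean())
            improved += matched_gap <= full_gap + 1e-9
        assert improved == 20

    def test_matched_groups_equal_size(self, study_cohort):
        report = build_reports(study_cohort)
        assert len(report.matched_case_ids) == len(report.matched_control_ids) == 10
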