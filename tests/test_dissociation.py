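"""Dissociation regression, derived exposure effects, Welch comparisons."""

import numpy as np
import pandas as pd
import pytest

from sternmag import dissociation, synthetic_rt
from sternmag.dissociation import (
    FitError,
    cell_means,
    compare_groups,
    derived_effects,
    derived_effects_from_coefficients,
    error_omission_summary,
    fit_on_cell_means,
    fit_sternberg,
    welch_test,
)
from sternmag.synthetic_rt import GeneratorParams, simulate_cohort


def records_frame(sz, tg, ex, rt, outcome="correct", subject="S1"):
    n = len(rt)
    return pd.DataFrame(
        {
            "subject_id": [subject] * n if isinstance(subject, str) else subject,
            "exposed": ex,
            "block_sz": sz,
            "is_target": tg,
            "trial_index": range(n),
            "rt_ms": rt,
            "outcome": [outcome] * n if isinstance(outcome, str) else outcome,
        }
    )


def brute_force_ols(X, y):
    """Independent oracle: normal equations solved directly."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, se


class TestFit:
    def test_hand_solved_toy_design(self):
        # one row per (SZ, TG) at EX=0 with an exact linear rule
        sz = np.repeat([1, 2, 3, 4], 2)
        tg = np.tile([0, 1], 4)
        rt = 400 + 20 * sz - 30 * tg
        fit = fit_sternberg(records_frame(sz, tg, 0, rt.astype(float)), "eq1")
        assert fit.coefficients["intercept"] == pytest.approx(400, abs=1e-9)
        assert fit.coefficients["SZ"] == pytest.approx(20, abs=1e-9)
        assert fit.coefficients["TG"] == pytest.approx(-30, abs=1e-9)
        assert fit.resid_sd_hat == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_cohort_recovers_truth_exactly(self, noiseless_records):
        fit = fit_sternberg(noiseless_records, "eq2")
        truth = GeneratorParams().as_coefficients()
        for term, key in zip(
            ("intercept", "SZ", "EX", "SZxEX", "TG"),
            ("beta0", "beta1", "beta2", "beta3", "beta4"),
        ):
            assert fit.coefficients[term] == pytest.approx(truth[key], abs=1e-9)

    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 11))
            sz = rng.integers(1, 5, n)
            tg = rng.integers(0, 2, n)
            ex = rng.integers(0, 2, n)
            rt = 400 + 20 * sz + rng.normal(0, 30, n)
            frame = records_frame(sz, tg, ex, rt)
            model = "eq2" if len(set(ex)) == 2 else "eq1"
            X = dissociation.design_matrix(frame, model)
            if np.linalg.matrix_rank(X) < X.shape[1] or n <= X.shape[1]:
                continue
            beta, se = brute_force_ols(X, rt)
            fit = fit_sternberg(frame, model)
            np.testing.assert_allclose(list(fit.coefficients.values()), beta, atol=1e-8)
            np.testing.assert_allclose(list(fit.std_errors.values()), se, atol=1e-8)

    def test_exposure_model_reduces_to_baseline_model_at_ex0(self, cohort_plan):
        # With the 6/6 target balance intact (no exclusions), the centred
        # target column is orthogonal to the exposure terms, so the full
        # model's SZ slope and target-balanced intercept (b0 + b4/2) are
        # determined by the sham rows alone and equal the baseline-model fit
        # on that subset exactly.  The raw intercepts differ by half the gap
        # between the pooled and sham-only target coefficients.
        tbl = simulate_cohort(cohort_plan, GeneratorParams(p_error=0.0), seed=17)
        assert set(tbl["outcome"]) == {"correct"}
        fit2 = fit_sternberg(tbl, "eq2")
        fit1 = fit_sternberg(tbl[tbl["exposed"] == 0], "eq1")
        assert fit2.coefficients["SZ"] == pytest.approx(fit1.coefficients["SZ"], abs=1e-9)
        balanced2 = fit2.coefficients["intercept"] + 0.5 * fit2.coefficients["TG"]
        balanced1 = fit1.coefficients["intercept"] + 0.5 * fit1.coefficients["TG"]
        assert balanced2 == pytest.approx(balanced1, abs=1e-9)
        assert fit2.coefficients["TG"] == pytest.approx(
            fit1.coefficients["TG"], abs=4 * fit2.std_errors["TG"]
        )

    def test_nested_models_identical_in_the_noiseless_limit(self, noiseless_records):
        fit2 = fit_sternberg(noiseless_records, "eq2")
        fit1 = fit_sternberg(noiseless_records[noiseless_records["exposed"] == 0], "eq1")
        for pair in (("intercept", "intercept"), ("SZ", "SZ"), ("TG", "TG")):
            assert fit2.coefficients[pair[0]] == pytest.approx(
                fit1.coefficients[pair[1]], abs=1e-9
            )

    def test_stochastic_recovery_of_scanning_slope(self, noisy_records):
        fit = fit_sternberg(noisy_records, "eq2")
        assert abs(fit.coefficients["SZ"] - 19.4) < 2 * fit.std_errors["SZ"]

    def test_cell_mean_fit_reproduces_trial_level_fit(self, noisy_records):
        trial_fit = fit_sternberg(noisy_records, "eq2")
        cm_fit = fit_on_cell_means(noisy_records, "eq2")
        np.testing.assert_allclose(
            list(cm_fit.coefficients.values()),
            list(trial_fit.coefficients.values()),
            atol=1e-8,
        )

    def test_degenerate_designs_signalled(self, noisy_records):
        one_sz = noisy_records[noisy_records["block_sz"] == 2]
        with pytest.raises(FitError):
            fit_sternberg(one_sz, "eq1")
        sham_only = noisy_records[noisy_records["exposed"] == 0]
        with pytest.raises(FitError):
            fit_sternberg(sham_only, "eq2")
        with pytest.raises(FitError):
            fit_sternberg(noisy_records.iloc[0:0], "eq2")

    def test_error_and_omission_rows_excluded_by_default(self, noisy_records):
        fit = fit_sternberg(noisy_records, "eq2")
        n_correct = (noisy_records["outcome"] == "correct").sum()
        assert fit.n_used == n_correct
        assert fit.excluded["error"] == (noisy_records["outcome"] == "error").sum()
        incl = fit_sternberg(noisy_records, "eq2", include_error_rts=True)
        assert incl.n_used >= fit.n_used


class TestDerivedEffects:
    def test_scan_ratio_from_study_coefficients(self):
        eff = derived_effects_from_coefficients(428.0, 19.4, -15.0, 6.3)
        assert round(eff.scan_ratio, 2) == 0.32
        assert eff.scan_inflation == pytest.approx(1.0 + eff.scan_ratio, abs=0)

    def test_percent_intercept_change(self):
        # discussion-section variant of the estimates
        eff = derived_effects_from_coefficients(428.1, 19.4, -15.4, 6.3)
        assert round(eff.percent_beta0_change, 1) == 3.6

    def test_net_exposure_delay_by_set_size(self):
        eff = derived_effects_from_coefficients(428.0, 19.4, -15.0, 6.3)
        assert eff.delta_rt_by_sz[1] == pytest.approx(-8.7)
        assert eff.delta_rt_by_sz[4] == pytest.approx(-15.0 + 6.3 * 4)

    def test_zero_slope_signalled(self):
        with pytest.raises(ZeroDivisionError):
            derived_effects_from_coefficients(400.0, 0.0, -15.0, 6.3)

    def test_requires_exposure_model(self, noisy_records):
        fit1 = fit_sternberg(noisy_records[noisy_records["exposed"] == 0], "eq1")
        with pytest.raises(ValueError):
            derived_effects(fit1)


class TestCellMeans:
    def test_constant_records(self):
        combos = np.array(
            [(ex, tg, sz) for ex in (0, 1) for tg in (0, 1) for sz in (1, 2, 3, 4)]
        )
        combos = np.repeat(combos, 2, axis=0)
        ex, tg, sz = combos.T
        cm = cell_means(records_frame(sz, tg, ex, np.full(32, 500.0)))
        assert len(cm) == 16
        assert (cm["mean_rt_ms"] == 500.0).all()
        assert (cm["sem"] == 0.0).all()

    def test_large_sample_cell_mean_near_model_mean(self, cohort_plan):
        params = GeneratorParams(p_error=0.0)
        tbl = simulate_cohort(cohort_plan, params, seed=13)
        cm = cell_means(tbl).set_index(["exposed", "is_target", "block_sz"])
        cell = cm.loc[(1, 0, 4)]
        assert abs(cell["mean_rt_ms"] - 515.8) < 3 * cell["sem"]

    def test_counts_are_bookkept(self):
        sz = np.array([1, 2, 1, 2])
        frame = records_frame(
            sz, [0, 0, 0, 0], 0, [400.0, 420.0, 410.0, 430.0],
            subject=["A", "A", "B", "B"],
        )
        cm = cell_means(frame)
        present = cm[cm["n"] > 0]
        assert present["n"].tolist() == [2, 2]

    def test_empty_cells_reported_with_zero_n(self):
        frame = records_frame([1, 2], [0, 0], [0, 1], [400.0, 500.0])
        cm = cell_means(frame)
        empties = cm[cm["n"] == 0]
        assert len(empties) == 2  # (0,0,2) and (1,0,1) never observed
        assert empties["mean_rt_ms"].isna().all()


class TestWelch:
    def test_age_row_summary_statistics(self):
        cmp_ = welch_test(22.8, 2.5, 31, 23.6, 2.3, 34, variable="age")
        assert round(cmp_.ci95[0], 1) == -2.0
        assert round(cmp_.ci95[1], 1) == 0.4
        # non-significant, as the summary table reports (its rounded p differs
        # slightly from the Welch value implied by its own summary statistics)
        assert 0.05 < cmp_.p < 0.25
        assert cmp_.p == pytest.approx(0.186, abs=0.002)

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import ttest_ind_from_stats

        for _ in range(10):
            ma, mb = rng.normal(0, 5, 2)
            sa, sb = rng.uniform(0.5, 4, 2)
            na, nb = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            ours = welch_test(ma, sa, na, mb, sb, nb)
            ref = ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_groups_symmetric_ci(self):
        cmp_ = welch_test(10.0, 2.0, 20, 10.0, 2.0, 20)
        assert cmp_.mean_diff == 0.0
        assert cmp_.ci95[0] == pytest.approx(-cmp_.ci95[1])

    def test_swapping_groups_negates_difference(self):
        a = welch_test(22.8, 2.5, 31, 23.6, 2.3, 34)
        b = welch_test(23.6, 2.3, 34, 22.8, 2.5, 31)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.ci95[0] == pytest.approx(-b.ci95[1])
        assert a.p == pytest.approx(b.p)

    def test_degenerate_equal_constants(self):
        cmp_ = welch_test(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert cmp_.p == 1.0 and cmp_.mean_diff == 0.0

    def test_profile_comparisons_cover_all_variables(self, cohort_plan):
        prof = synthetic_rt.generate_profiles(cohort_plan, seed=4)
        table = compare_groups(prof)
        assert len(table) == len(synthetic_rt.DEFAULT_PROFILE_VARS)
        assert ((table["ci95_low"] <= table["ci95_high"]).all())


class TestErrorOmissionSummary:
    def test_no_errors_anywhere(self, noiseless_records):
        summary = error_omission_summary(noiseless_records)
        assert (summary["mean"] == 0.0).all()

    def test_hand_computed_two_subject_case(self):
        outcomes = ["error"] * 3 + ["correct"] * 45 + ["error"] * 5 + ["correct"] * 43
        frame = records_frame(
            np.tile([1, 2, 3, 4], 24),
            0, 0, np.full(96, 450.0),
            outcome=outcomes,
            subject=["A"] * 48 + ["B"] * 48,
        )
        summary = error_omission_summary(frame).set_index(["type", "exposed"])
        assert summary.loc[("error", 0), "mean"] == pytest.approx(4.0)
        assert summary.loc[("error", 0), "sd"] == pytest.approx(np.sqrt(2.0))

    def test_group_error_means_near_binomial_expectation(self, noisy_records):
        summary = error_omission_summary(noisy_records)
        errs = summary[summary["type"] == "error"]
        assert errs["mean"].between(5.5, 9.0).all()  # 48 * 0.15 = 7.2
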