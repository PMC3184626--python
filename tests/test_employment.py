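import numpy as np
import pandas as pd
import pytest

from cfsme_costs import cohort, employment, scores, synth
from cfsme_costs.employment import (
    chi2_independence,
    cochran_armitage_trend,
    fit_logistic,
    two_sample_t,
)

#: employed / discontinued counts by sex from the published comparison
SEX_TABLE = {"female": (643, 743), "male": (168, 255)}
AGE_TABLE = {
    "employed": [59, 153, 265, 202, 119, 13],
    "discontinued": [44, 154, 250, 269, 225, 56],
}


def _two_by_two_frame(counts: dict[str, tuple[int, int]]) -> tuple[pd.DataFrame, pd.Series]:
    """Expand sex x outcome counts into a design with intercept + female."""
    rows, ys = [], []
    for sex, (n_emp, n_disc) in counts.items():
        female = 1.0 if sex == "female" else 0.0
        rows += [[1.0, female]] * (n_emp + n_disc)
        ys += [0.0] * n_emp + [1.0] * n_disc
    X = pd.DataFrame(rows, columns=["intercept", "female"])
    return X, pd.Series(ys)


class TestAssociationTests:
    def test_sex_by_status_chi2_matches_published_p(self):
        table = np.array([[643, 168], [743, 255]])
        res = chi2_independence(table)
        assert res.statistic == pytest.approx(5.840464761, rel=1e-6)
        assert 0.01 < res.p_value < 0.03

    def test_age_band_chi2_is_highly_significant(self):
        table = np.array([AGE_TABLE["employed"], AGE_TABLE["discontinued"]])
        assert chi2_independence(table).p_value < 0.001

    def test_identical_balanced_groups_give_p_one(self):
        res = chi2_independence(np.array([[50, 50], [50, 50]]))
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_directs_to_exact_alternative(self):
        with pytest.raises(ValueError, match="exact"):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_trend_statistic_against_hand_computation(self):
        # successes (1,2,3) of (5,5,5): z = 2 / sqrt(0.24 * 10)
        res = cochran_armitage_trend([1, 2, 3], [5, 5, 5])
        assert res.statistic == pytest.approx(2 / np.sqrt(2.4), rel=1e-12)

    def test_dispatcher_covers_table_variables(self, sim_scored):
        assert employment.test_association(sim_scored, "sex").method == "chi2"
        assert employment.test_association(sim_scored, "age_band").method == "chi2"
        assert employment.test_association(sim_scored, "duration_illness").method == "t"
        assert employment.test_association(sim_scored, "assessment_year").method == "trend"


class TestLogisticFit:
    @pytest.mark.parametrize(
        "counts",
        [
            SEX_TABLE,
            {"female": (30, 10), "male": (12, 25)},
            {"female": (5, 9), "male": (7, 3)},
        ],
    )
    def test_two_by_two_fit_equals_closed_form_cross_ratio(self, counts):
        X, y = _two_by_two_frame(counts)
        fit = fit_logistic(X, y)
        (fe, fd), (me, md) = counts["female"], counts["male"]
        assert fit.odds_ratios["female"] == pytest.approx(
            (fd * me) / (fe * md), abs=1e-6
        )

    def test_published_sex_counts_give_crude_or_076(self):
        X, y = _two_by_two_frame(SEX_TABLE)
        fit = fit_logistic(X, y)
        assert fit.odds_ratios["female"] == pytest.approx(0.7612844, abs=1e-6)

    def test_agrees_with_statsmodels_mle(self, sim_scored):
        import statsmodels.api as sm

        X, y = employment.build_design(sim_scored)
        fit = fit_logistic(X, y)
        ref = sm.Logit(np.asarray(y), X.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)

    def test_log_likelihood_ascends_across_iterations(self, sim_scored):
        X, y = employment.build_design(sim_scored)
        fit = fit_logistic(X, y)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-8)
        assert fit.converged

    def test_record_order_does_not_move_estimates(self, sim_scored):
        X, y = employment.build_design(sim_scored)
        fit = fit_logistic(X, y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit2 = fit_logistic(X.iloc[perm], y.iloc[perm])
        np.testing.assert_allclose(
            fit.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10
        )

    def test_complete_separation_is_flagged_not_silent(self):
        X = pd.DataFrame({"intercept": 1.0, "x": np.r_[np.zeros(20), np.ones(20)]})
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)])
        with pytest.warns(employment.SeparationWarning):
            fit = fit_logistic(X, y)
        assert not fit.converged

    def test_rank_deficiency_names_the_collinear_column(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "x": x, "x_copy": x})
        y = pd.Series((rng.random(50) < 0.5).astype(float))
        with pytest.raises(ValueError, match="x_copy|x"):
            fit_logistic(X, y)

    def test_null_covariate_or_tends_to_one(self):
        rng = np.random.default_rng(2)
        n = 20000
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = pd.Series((rng.random(n) < 0.5).astype(float))
        fit = fit_logistic(X, y)
        assert fit.odds_ratios["x"] == pytest.approx(1.0, abs=0.05)

    def test_wald_interval_brackets_the_odds_ratio(self, sim_scored):
        fit = employment.fully_adjusted_model(sim_scored)
        ci = fit.conf_int
        assert (ci["or_low"] <= fit.odds_ratios).all()
        assert (fit.odds_ratios <= ci["or_high"]).all()


class TestModelSpecifications:
    def test_parameter_recovery_on_large_synthetic_cohort(self):
        cfg = synth.SimulationConfig(
            n_patients=50_000,
            complete_inventory_prob=1.0,
            duration_missing_prob=0.0,
            vas_missing_prob=0.0,
            status_recorded_prob=1.0,
            prob_other_given_recorded=0.0,
        )
        scored = scores.score_table(synth.simulate_cohort(cfg, seed=7))
        fit = employment.fully_adjusted_model(scored)
        truth = synth.true_parameters(cfg).coefficients
        for name in employment.DEFAULT_COVARIATES:
            z = abs(fit.params[name] - truth[name]) / fit.bse[name]
            assert z < 3, f"{name}: z-deviation {z:.2f}"

    def test_single_active_covariate_drives_only_its_partial_or(self):
        coef = {k: 0.0 for k in synth._default_coefficients()}
        coef["age_decade"] = 0.27
        cfg = synth.SimulationConfig(
            n_patients=30_000,
            coefficients=coef,
            complete_inventory_prob=1.0,
            duration_missing_prob=0.0,
            vas_missing_prob=0.0,
            status_recorded_prob=1.0,
            prob_other_given_recorded=0.0,
        )
        scored = scores.score_table(synth.simulate_cohort(cfg, seed=11))
        partial = employment.partially_adjusted_models(scored)
        age_or = partial["age_decade"].odds_ratios["age_decade"]
        assert age_or == pytest.approx(np.exp(0.27), rel=0.07)
        for name in ("duration_years", "vas_pain"):
            fit = partial[name]
            assert fit.odds_ratios[name] == pytest.approx(1.0, abs=0.06)

    def test_partial_fits_are_deterministic_across_calls(self, sim_scored):
        a = employment.partially_adjusted_models(sim_scored)
        b = employment.partially_adjusted_models(sim_scored)
        for name in a:
            pd.testing.assert_series_equal(a[name].params, b[name].params)

    def test_fully_adjusted_reports_the_complete_case_n(self, sim_scored):
        X, y = employment.build_design(sim_scored)
        fit = employment.fully_adjusted_model(sim_scored)
        assert fit.n == len(y)
        covs = employment.covariate_frame(sim_scored)
        outcome = employment.resolve_outcome(sim_scored)
        expected = int(
            (outcome.notna() & covs[list(employment.DEFAULT_COVARIATES)].notna().all(axis=1)).sum()
        )
        assert fit.n == expected


class TestGroupSummary:
    def test_quantile_matched_durations_reproduce_the_printed_medians(self):
        # engineer employed-group durations with quartiles (15, 35, 84)
        emp = [15.0, 15.0, 35.0, 84.0, 84.0]
        frame = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(10)],
                "centre": "c",
                "assessment_year": 2007,
                "age": 30,
                "sex": "female",
                "duration_illness": emp + [48.0] * 5,
                "employment_status": ["currently_employed"] * 5
                + ["indefinitely_discontinued"] * 5,
                "chalder_total": np.nan, "sf36pf_total": np.nan,
                "hads_anxiety": np.nan, "hads_depression": np.nan,
                "vas_pain": np.nan,
            }
        )
        summary = employment.summarize_by_employment(frame)
        row = summary.continuous.loc["duration_illness"]
        assert row["median_employed"] == 35.0
        assert (row["q1_employed"], row["q3_employed"]) == (15.0, 84.0)

    def test_identical_groups_summarise_identically(self, sim_scored):
        summary = employment.summarize_by_employment(sim_scored)
        cont = summary.continuous
        assert (cont.filter(like="n_") <= max(summary.n_employed, summary.n_discontinued)).all().all()

    def test_singleton_group_degenerate_iqr(self):
        frame = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "centre": "c", "assessment_year": 2007, "age": 30,
                "sex": "female", "duration_illness": [12.0, 24.0],
                "employment_status": ["currently_employed", "temporarily_discontinued"],
                "chalder_total": np.nan, "sf36pf_total": np.nan,
                "hads_anxiety": np.nan, "hads_depression": np.nan, "vas_pain": np.nan,
            }
        )
        row = employment.summarize_by_employment(frame).continuous.loc["duration_illness"]
        assert row["median_employed"] == row["q1_employed"] == row["q3_employed"] == 12.0

    def test_categorical_percentages_sum_to_100_across_groups(self, sim_scored):
        cat = employment.summarize_by_employment(sim_scored).categorical
        sums = cat["pct_employed"] + cat["pct_discontinued"]
        np.testing.assert_allclose(sums.dropna(), 100.0)
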