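"""Kaplan-Meier, Cox fitting, IPCW Brier machinery, and the bootstrap
model-comparison stage."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from neofit.survival_eval import (
    MODEL_SPECS,
    KaplanMeier,
    PredictionErrorCurve,
    SurvivalModelSpec,
    bootstrap_632plus,
    brier_curve,
    crossval_ks,
    fit_cox,
    integrated_brier,
    km_estimator,
    logrank_test,
    quantile_groups,
    weight_632plus,
)
from neofit.synthetic_data import CohortConfig, generate_cohort


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        km = km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival(1.5) == pytest.approx(2.0 / 3.0)
        assert km.survival(0.5) == 1.0
        assert km.survival(3.0) == 0.0

    def test_all_censored_is_unity(self):
        km = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km.survival(np.array([0.0, 2.0, 10.0])) == 1.0)

    def test_single_event_among_five(self):
        km = km_estimator([5.0, 6.0, 7.0, 8.0, 9.0], [1, 0, 0, 0, 0])
        assert km.survival(5.0) == pytest.approx(0.8)
        assert km.survival_left(5.0) == 1.0

    def test_matches_lifelines_on_censored_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10.0, 200)
        c = rng.exponential(15.0, 200)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        ours = km_estimator(times, events)
        ref = KaplanMeierFitter().fit(times, events)
        grid = np.quantile(times, [0.1, 0.3, 0.5, 0.7, 0.9])
        expected = ref.survival_function_at_times(grid).to_numpy()
        assert ours.survival(grid) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([], [])


class TestQuantileGroups:
    def test_percentile_convention_on_1_to_100(self):
        scores = np.arange(1, 101)
        labels = quantile_groups(scores)
        assert set(scores[labels == "low"]) == set(range(1, 16))
        assert set(scores[labels == "high"]) == set(range(86, 101))

    def test_minimum_cohort_has_nonempty_extremes(self):
        labels = quantile_groups(np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.6]))
        assert (labels == "low").sum() >= 1 and (labels == "high").sum() >= 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        perm = rng.permutation(40)
        labels = quantile_groups(scores)
        labels_perm = quantile_groups(scores[perm])
        assert np.array_equal(labels[perm], labels_perm)

    def test_boundary_ties_included_on_boundary_side(self):
        scores = np.array([1.0] * 5 + list(range(2, 22)))
        labels = quantile_groups(scores)
        assert np.all(labels[:5] == "low")

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            quantile_groups(np.ones(20))


class TestLogrank:
    def test_identical_groups_not_separated(self):
        times = np.tile([5.0, 8.0, 12.0, 20.0, 30.0], 2)
        events = np.tile([1, 1, 0, 1, 0], 2)
        labels = np.array(["low"] * 5 + ["high"] * 5)
        chi2, p = logrank_test(times, events, labels)
        assert p > 0.9

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 60)
        events = np.ones(60, dtype=int)
        labels = np.array(["low"] * 30 + ["high"] * 30)
        swapped = np.array(["high"] * 30 + ["low"] * 30)
        chi2_a, _ = logrank_test(times, events, labels)
        chi2_b, _ = logrank_test(times, events, swapped)
        assert chi2_a == pytest.approx(chi2_b)

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 20
        for _ in range(reps):
            t_low = rng.exponential(30.0, 200)
            t_high = rng.exponential(10.0, 200)
            times = np.concatenate([t_low, t_high])
            events = np.ones(400, dtype=int)
            labels = np.array(["low"] * 200 + ["high"] * 200)
            _, p = logrank_test(times, events, labels)
            rejections += p < 0.05
        assert rejections >= int(0.95 * reps)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["low", "low"])


class TestFitCox:
    def test_protective_effect_recovered(self):
        # average over independent cohorts: a single realization carries
        # sampling noise of SD ~ 0.06 around the planted coefficient
        estimates = []
        for seed in range(3):
            df = generate_cohort(
                CohortConfig(n_patients=500, seed=seed, beta_cyt=-0.8)
            ).patients
            estimates.append(fit_cox(df, MODEL_SPECS["cyt_tmb"]).coefficients["cyt"])
        assert np.mean(estimates) == pytest.approx(-0.8, abs=0.15)

    def test_null_covariate_calibrated(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            df = generate_cohort(
                CohortConfig(
                    n_patients=400,
                    seed=100 + seed,
                    beta_cyt=0.0,
                    beta_tmb=0.0,
                    beta_imm=0.0,
                    beta_stage=0.0,
                )
            ).patients
            model = fit_cox(df, MODEL_SPECS["tmb"])
            beta = model.coefficients["tmb"]
            se = model.standard_errors["tmb"]
            hits += abs(beta) < 2 * se
        assert hits >= int(0.9 * reps)

    def test_duplicating_patients_leaves_coefficients(self):
        # exact invariance holds for the partial likelihood; the Efron tie
        # correction perturbs it slightly once every time is duplicated
        df = generate_cohort(CohortConfig(n_patients=150, seed=2)).patients
        doubled = pd.concat([df, df], ignore_index=True)
        a = fit_cox(df, MODEL_SPECS["cyt_tmb"]).coefficients
        b = fit_cox(doubled, MODEL_SPECS["cyt_tmb"]).coefficients
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=0.02)

    def test_reference_predicts_km_curve(self):
        df = generate_cohort(CohortConfig(n_patients=80, seed=3)).patients
        model = fit_cox(df, MODEL_SPECS["reference"])
        grid = np.quantile(df["time"], [0.2, 0.5, 0.8])
        surv = model.predict_survival(df, grid)
        km = KaplanMeier(df["time"], df["event"])
        assert np.allclose(surv, np.tile(km.survival(grid), (len(df), 1)))

    def test_ph_check_reports_each_covariate(self):
        df = generate_cohort(CohortConfig(n_patients=200, seed=4)).patients
        model = fit_cox(df, MODEL_SPECS["cyt_tmb"])
        checks = model.ph_check()
        assert set(checks) == {"cyt", "tmb", "stage"}
        for r, p in checks.values():
            assert np.isfinite(r) and 0.0 <= p <= 1.0


def _uncensored_frame(rng, n=120):
    times = rng.exponential(100.0, n)
    return times, np.ones(n, dtype=int)


class TestBrier:
    def test_uncensored_equals_plain_mse(self):
        rng = np.random.default_rng(8)
        times, events = _uncensored_frame(rng)
        grid = np.quantile(times, np.linspace(0.05, 0.8, 12))
        surv = rng.uniform(0.0, 1.0, size=(times.size, grid.size))
        curve = brier_curve(surv, times, events, grid)
        alive = times[:, None] > grid[None, :]
        mse = ((alive.astype(float) - surv) ** 2).mean(axis=0)
        assert curve.brier == pytest.approx(mse, abs=1e-15)

    def test_perfect_oracle_gives_zero(self):
        rng = np.random.default_rng(9)
        times, events = _uncensored_frame(rng)
        grid = np.quantile(times, np.linspace(0.05, 0.8, 10))
        surv = (times[:, None] > grid[None, :]).astype(float)
        curve = brier_curve(surv, times, events, grid)
        assert np.all(curve.brier == 0.0)

    def test_constant_prediction_reduces_to_binomial_mse(self):
        rng = np.random.default_rng(10)
        times, events = _uncensored_frame(rng)
        grid = np.array([np.median(times)])
        p = 0.7
        surv = np.full((times.size, 1), p)
        curve = brier_curve(surv, times, events, grid)
        alive = (times > grid[0]).astype(float)
        assert curve.brier[0] == pytest.approx(np.mean((alive - p) ** 2))

    def test_matches_scikit_survival_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv

        rng = np.random.default_rng(11)
        n = 250
        t = rng.exponential(100.0, n)
        c = rng.exponential(200.0, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        grid = np.quantile(times, np.linspace(0.1, 0.7, 8))
        surv = np.clip(rng.uniform(0.05, 0.95, size=(n, grid.size)), 0, 1)
        curve = brier_curve(surv, times, events, grid)
        y = Surv.from_arrays(events.astype(bool), times)
        _, ref = sksurv_metrics.brier_score(y, y, surv, grid)
        assert curve.brier == pytest.approx(ref, abs=1e-10)

    def test_ipcw_tracks_latent_error_under_censoring(self):
        """IPCW Brier of censored data approximates the uncensored MSE
        computed on the latent event times."""
        df = generate_cohort(CohortConfig(n_patients=2000, seed=12)).patients
        times = df["time"].to_numpy()
        events = df["event"].to_numpy()
        latent = df["latent_time"].to_numpy()
        grid = np.quantile(times, np.linspace(0.1, 0.7, 6))
        model = fit_cox(df, MODEL_SPECS["cyt_tmb"])
        surv = model.predict_survival(df, grid)
        ipcw = brier_curve(surv, times, events, grid).brier
        truth = (
            ((latent[:, None] > grid[None, :]).astype(float) - surv) ** 2
        ).mean(axis=0)
        assert ipcw == pytest.approx(truth, abs=0.02)

    def test_zero_censoring_weight_truncates_grid(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0])
        grid = np.array([1.5, 5.0])  # beyond the last censoring time
        surv = np.full((4, 2), 0.5)
        with pytest.warns(UserWarning, match="truncating"):
            curve = brier_curve(surv, times, events, grid)
        assert curve.times.size == 1


class TestIntegratedBrier:
    def test_constant_curve_integrates_to_itself(self):
        curve = PredictionErrorCurve("m", np.linspace(0.0, 10.0, 6), np.full(6, 0.3), 10.0)
        assert integrated_brier(curve) == pytest.approx(0.3)

    def test_linear_curve_integrates_to_half_slope(self):
        t = np.linspace(0.0, 10.0, 11)
        curve = PredictionErrorCurve("m", t, 0.4 * t / 10.0, 10.0)
        assert integrated_brier(curve) == pytest.approx(0.2)

    def test_first_interval_reproduces_local_average(self):
        t = np.array([0.0, 2.0, 8.0])
        b = np.array([0.1, 0.3, 0.9])
        curve = PredictionErrorCurve("m", t, b, 8.0)
        assert integrated_brier(curve, tmax=2.0) == pytest.approx(0.2)


@pytest.fixture(scope="module")
def cohort_df():
    return generate_cohort(CohortConfig(n_patients=150, seed=20)).patients


class TestBootstrap632Plus:
    def test_weight_formula_limits(self):
        assert weight_632plus(0.0) == 0.632
        assert weight_632plus(1.0) == pytest.approx(1.0)
        assert weight_632plus(-5.0) == 0.632  # clipped

    def test_seed_determinism(self, cohort_df):
        specs = [MODEL_SPECS["reference"], MODEL_SPECS["tmb"]]
        a = bootstrap_632plus(specs, cohort_df, B=10, seed=5)
        b = bootstrap_632plus(specs, cohort_df, B=10, seed=5)
        assert a.ibs == b.ibs
        assert np.array_equal(
            a.curves["tmb"].brier, b.curves["tmb"].brier
        )

    def test_identical_specs_compare_flat(self, cohort_df):
        twin = SurvivalModelSpec("tmb_twin", ("tmb",))
        res = bootstrap_632plus(
            [MODEL_SPECS["tmb"], twin], cohort_df, B=10, seed=6
        )
        assert res.comparisons[("tmb", "tmb_twin")] == pytest.approx(1.0)
        assert res.ibs["tmb"] == pytest.approx(res.ibs["tmb_twin"])

    def test_blended_error_between_zero_and_one(self, cohort_df):
        res = bootstrap_632plus(
            [MODEL_SPECS["reference"], MODEL_SPECS["cyt_tmb"]],
            cohort_df,
            B=10,
            seed=7,
        )
        for curve in res.curves.values():
            assert np.all(curve.brier >= 0.0) and np.all(curve.brier <= 1.0)

    def test_informative_covariate_beats_reference(self):
        """A planted protective covariate reduces out-of-sample error."""
        df = generate_cohort(
            CohortConfig(n_patients=300, seed=21, beta_cyt=-0.8)
        ).patients
        res = bootstrap_632plus(
            [MODEL_SPECS["reference"], MODEL_SPECS["cyt_tmb"]],
            df,
            B=40,
            seed=8,
            compare="ibs",
        )
        assert res.ibs["cyt_tmb"] < res.ibs["reference"]
        assert res.comparisons[("cyt_tmb", "reference")] < 0.05


class TestCrossvalKs:
    def test_identical_specs_not_separated(self):
        df = generate_cohort(CohortConfig(n_patients=150, seed=22)).patients
        twin = SurvivalModelSpec("tmb_twin", ("tmb",))
        res, _ = crossval_ks(MODEL_SPECS["tmb"], twin, df, iterations=15, seed=9)
        assert res.pvalue > 0.5

    def test_planted_covariate_separates_from_noise_model(self):
        df = generate_cohort(
            CohortConfig(n_patients=250, seed=23, beta_cyt=-0.9)
        ).patients
        res, samples = crossval_ks(
            MODEL_SPECS["cyt_tmb"], MODEL_SPECS["tmb_i"], df, iterations=30, seed=10
        )
        assert np.median(samples["cyt_tmb"]) < np.median(samples["tmb_i"])
        assert res.pvalue < 0.05

    def test_seed_determinism(self):
        df = generate_cohort(CohortConfig(n_patients=120, seed=24)).patients
        a, sa = crossval_ks(
            MODEL_SPECS["tmb"], MODEL_SPECS["reference"], df, iterations=12, seed=11
        )
        b, sb = crossval_ks(
            MODEL_SPECS["tmb"], MODEL_SPECS["reference"], df, iterations=12, seed=11
        )
        assert a.pvalue == b.pvalue
        assert np.array_equal(sa["tmb"], sb["tmb"])
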