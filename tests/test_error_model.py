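"""Reporting-error model: percentiles, polynomial fit, CV order selection,
sigma estimation and the Goldfeld-Quandt homoskedasticity check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutribias.error_model import (
    ErrorModel,
    PercentileRef,
    empirical_percentile,
    estimate_sigma,
    fit_error_model,
    fit_mean_error,
    goldfeld_quandt,
    mean_error,
    select_order_cv,
)
from nutribias.models import NUTRIENT_COLUMNS


class TestPercentile:
    def test_median_under_hazen_convention(self):
        ref = PercentileRef.from_sample([10.0, 20.0, 30.0])
        assert empirical_percentile(ref, 20.0) == pytest.approx(0.5)

    def test_below_range_clamps_to_minimum(self):
        ref = PercentileRef.from_sample([10.0, 20.0, 30.0])
        assert empirical_percentile(ref, 5.0) == pytest.approx(1 / 6)

    def test_maximum_of_large_sample(self, rng):
        draws = rng.normal(size=303)
        ref = PercentileRef.from_sample(draws)
        assert empirical_percentile(ref, draws.max()) == pytest.approx((303 - 0.5) / 303)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            PercentileRef.from_sample([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40), st.data())
    @settings(derandomize=True, max_examples=60)
    def test_monotone_and_bounded(self, sample, data):
        ref = PercentileRef.from_sample(sample)
        x1 = data.draw(st.floats(-2e3, 2e3))
        x2 = data.draw(st.floats(-2e3, 2e3))
        p1, p2 = empirical_percentile(ref, x1), empirical_percentile(ref, x2)
        assert 0 < p1 < 1 and 0 < p2 < 1
        if x1 <= x2:
            assert p1 <= p2


class TestMeanError:
    def _model(self, coef):
        ref = PercentileRef.from_sample([1.0, 2.0])
        return ErrorModel(np.asarray(coef, float), order=len(coef) - 1, sigma=1.0, reference=ref)

    def test_zero_polynomial(self):
        model = self._model([0.0, 0.0])
        assert mean_error(model, 0.3) == 0.0

    @pytest.mark.parametrize(
        "coef, p, expected",
        [([-100.0, -500.0], 0.5, -350.0), ([0.0, 0.0, 0.0, 1.0], 0.5, 0.125)],
    )
    def test_polynomial_evaluation(self, coef, p, expected):
        assert mean_error(self._model(coef), p) == pytest.approx(expected)

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            mean_error(self._model([0.0, 1.0]), 1.5)


class TestFitMeanError:
    def test_exact_linear_recovery(self):
        p = np.linspace(0, 1, 20)
        e = 3.0 - 7.0 * p
        coef = fit_mean_error(p, e, order=1)
        np.testing.assert_allclose(coef, [3.0, -7.0], atol=1e-10)

    def test_constant_data_gives_constant_fit(self):
        p = np.linspace(0, 1, 30)
        coef = fit_mean_error(p, np.full(30, 4.2), order=3)
        assert coef[0] == pytest.approx(4.2, abs=1e-8)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-7)

    def test_interpolates_with_minimal_points(self):
        """K+1 distinct points determine the polynomial exactly; check against
        a direct linear solve of the Vandermonde system."""
        rng = np.random.default_rng(0)
        p = np.array([0.1, 0.45, 0.8])
        e = rng.normal(size=3)
        coef = fit_mean_error(p, e, order=2)
        oracle = np.linalg.solve(np.vander(p, 3, increasing=True), e)
        np.testing.assert_allclose(coef, oracle, atol=1e-9)

    def test_noisy_cubic_recovery_within_3_se(self, rng):
        truth = np.array([5.0, -40.0, 90.0, -60.0])
        n = 1000
        p = rng.uniform(size=n)
        sigma = 4.0
        e = np.polynomial.polynomial.polyval(p, truth) + sigma * rng.standard_normal(n)
        coef = fit_mean_error(p, e, order=3)
        # closed-form coefficient SEs from the design matrix
        X = np.vander(p, 4, increasing=True)
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma**2)
        assert np.all(np.abs(coef - truth) < 3 * se)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_mean_error(np.full(10, 0.5), np.arange(10.0), order=1)


class TestOrderSelection:
    def test_noiseless_linear_selects_order_one(self, rng):
        p = rng.uniform(size=200)
        e = 2.0 - 3.0 * p
        assert select_order_cv(p, e, folds=10, rng=rng) == 1

    def test_single_candidate_returned(self, rng):
        p = rng.uniform(size=50)
        e = rng.normal(size=50)
        assert select_order_cv(p, e, k_range={2}, folds=5, rng=rng) == 2

    def test_strong_cubic_selected_in_majority_of_seeds(self):
        truth = np.array([0.0, -300.0, 0.0, 800.0])
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            p = rng.uniform(size=303)
            e = np.polynomial.polynomial.polyval(p, truth) + 60.0 * rng.standard_normal(303)
            if select_order_cv(p, e, folds=10, rng=rng) == 3:
                hits += 1
        assert hits > n_seeds / 2

    def test_selected_order_minimizes_cv_mse(self, rng):
        p = rng.uniform(size=150)
        e = 1.0 - 2.0 * p + 0.5 * rng.standard_normal(150)
        selected, cv_mse = select_order_cv(p, e, folds=10, rng=rng, return_mse=True)
        assert cv_mse[selected] == min(cv_mse.values())

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            select_order_cv([0.1, 0.9], [1.0, 2.0], folds=10, rng=rng)


class TestSigma:
    def test_noiseless_polynomial_gives_zero_sigma(self):
        p = np.linspace(0, 1, 50)
        e = 1 + 2 * p
        coef = fit_mean_error(p, e, order=1)
        assert estimate_sigma(p, e, coef) == pytest.approx(0.0, abs=1e-10)

    def test_denominator_uses_residual_df(self):
        # residuals {-1, +1} around a constant fit embedded in a linear model:
        # SS = 2, df = n - (K+1) = 4 - 2 = 2 -> sigma = 1
        p = np.array([0.2, 0.4, 0.6, 0.8])
        e = np.array([-1.0, 1.0, -1.0, 1.0])
        coef = np.array([0.0, 0.0])
        assert estimate_sigma(p, e, coef) == pytest.approx(np.sqrt(4.0 / 2.0))

    def test_recovers_reporting_error_sd_within_2_percent(self, rng):
        """Parameter recovery at the energy-intake scale (sigma = 759.1)."""
        sigma_truth = 759.1
        n = 10000
        p = rng.uniform(size=n)
        e = -100.0 - 900.0 * p + sigma_truth * rng.standard_normal(n)
        coef = fit_mean_error(p, e, order=1)
        est = estimate_sigma(p, e, coef)
        assert abs(est - sigma_truth) / sigma_truth < 0.02


class TestGoldfeldQuandt:
    def test_discard_count_for_study_size(self, rng):
        e = rng.normal(size=303)
        o = rng.normal(size=303)
        _, _, n_discarded = goldfeld_quandt(e, o, middle_frac=0.2)
        assert n_discarded == 61

    def test_symmetric_variance_gives_unit_f(self):
        # middle two observations discarded; both tails are {-1, 1, -1, 1}
        e = np.array([-1.0, 1.0, -1.0, 1.0, 9.0, 9.0, -1.0, 1.0, -1.0, 1.0])
        o = np.arange(10.0)
        f, p, _ = goldfeld_quandt(e, o, middle_frac=0.2)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_type_one_error_near_alpha(self):
        """Under homoskedastic errors, the 5%-level rejection rate stays
        within binomial tolerance of 5% across seeded simulations."""
        n_sim, n = 1000, 303
        rng = np.random.default_rng(2023)
        rejections = 0
        for _ in range(n_sim):
            e = rng.standard_normal(n)
            o = rng.standard_normal(n)
            _, p, _ = goldfeld_quandt(e, o, middle_frac=0.2)
            rejections += p < 0.05
        rate = rejections / n_sim
        tol = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < tol

    def test_detects_strong_heteroskedasticity(self, rng):
        o = np.linspace(0, 1, 303)
        e = rng.standard_normal(303) * (0.2 + 3.0 * o)
        f, p, _ = goldfeld_quandt(e, o, middle_frac=0.2)
        assert f > 10 and p < 1e-6


class TestFitErrorModel:
    def test_linear_truth_recovered(self, rng):
        import pandas as pd

        n = 2000
        bio = rng.normal(2400, 490, size=n)
        rank = np.empty(n)
        rank[np.argsort(bio)] = np.arange(1, n + 1)
        p = (rank - 0.5) / n
        sr = bio + (150.0 - 1000.0 * p) + 300.0 * rng.standard_normal(n)
        cohort = pd.DataFrame({"sr": sr, "bio": bio})
        model = fit_error_model(cohort, "sr", "bio", rng=rng)
        assert model.order == 1
        np.testing.assert_allclose(model.coefficients, [150.0, -1000.0], rtol=0.15)
        assert model.sigma == pytest.approx(300.0, rel=0.05)

    def test_identical_sr_bio_gives_null_model(self, rng):
        import pandas as pd

        bio = rng.normal(100, 10, size=200)
        cohort = pd.DataFrame({"sr": bio.copy(), "bio": bio})
        model = fit_error_model(cohort, "sr", "bio", rng=rng)
        assert model.sigma == pytest.approx(0.0, abs=1e-8)
        p = np.linspace(0.01, 0.99, 13)
        np.testing.assert_allclose(model.mean(p), 0.0, atol=1e-8)

    def test_generator_truth_orders_recovered_in_majority(self):
        """Across seeded default synthetic cohorts (n=303) the CV-selected
        orders match the generating truths (1, 3, 3, 5) in the majority."""
        from nutribias.cohort import CohortConfig, generate

        truth = {"EI": 1, "SI": 3, "PoI": 3, "PrI": 5}
        hits = {nut: 0 for nut in truth}
        n_seeds = 11
        cfg = CohortConfig(n=303, pilot_n=10000)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cohort, _ = generate(cfg, rng=rng)
            for nut, (sr, bio) in NUTRIENT_COLUMNS.items():
                model = fit_error_model(cohort, sr, bio, rng=rng)
                hits[nut] += model.order == truth[nut]
        for nut, count in hits.items():
            assert count > n_seeds / 2, f"{nut}: recovered {count}/{n_seeds}"

    def test_roundtrip_serialization(self, source_cohort):
        cohort, _ = source_cohort
        model = fit_error_model(cohort, "ei_sr_kcal", "ei_bio_kcal", rng=np.random.default_rng(1))
        clone = ErrorModel.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.coefficients, model.coefficients)
        assert clone.order == model.order
        assert clone.sigma == pytest.approx(model.sigma)
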