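"""Monotone basis construction, penalized mixed-model fitting, prediction."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm

from ed50mcid.data_model import BETTER, NOT_BETTER, PHQ9, ObservationRecord
from ed50mcid.monotone_gamm import (
    ConfigurationError,
    DomainError,
    MonotoneSurface,
    SmoothSpec,
    _solve_joint,
    build_monotone_basis,
    fit_gamm,
    predict_probability,
)

RNG = np.random.default_rng(20210401)


def bernoulli_records(n, prob_fn, rng, scale=PHQ9, n_patients=None):
    """Records with change/baseline drawn broadly and y ~ Bernoulli(prob_fn)."""
    n_patients = n_patients or n
    records = []
    for i in range(n):
        baseline = int(rng.integers(1, scale.max_score + 1))
        change = int(rng.integers(baseline - scale.max_score, baseline + 1))
        better = rng.random() < prob_fn(change, baseline)
        records.append(
            ObservationRecord(
                patient_id=f"p{i % n_patients}",
                study_id="S",
                interval_index=i // n_patients + 1,
                scale=scale,
                baseline_score=baseline,
                followup_score=baseline - change,
                change=change,
                grc_raw="I feel slightly better" if better else "I feel about the same",
                grc_binary=BETTER if better else NOT_BETTER,
                grc_ordinal=2 if better else 3,
            )
        )
    return records


class TestBasis:
    def test_change_margin_is_nondecreasing_and_spans_range(self):
        basis = build_monotone_basis(SmoothSpec(), PHQ9)
        grid = np.linspace(-27, 27, 400)
        design = basis.change_design(grid)
        assert design.shape == (400, 8)
        assert np.diff(design, axis=0).min() >= -1e-10
        # integrated partition of unity: columns sum to the traversed length
        assert design[-1].sum() == pytest.approx(54.0)
        assert np.all(design[0] == 0.0)

    def test_zero_change_coefficients_give_constant_predictor_in_change(self):
        basis = build_monotone_basis(SmoothSpec(), PHQ9)
        theta = np.zeros(basis.n_coef)
        theta[0] = 0.7
        theta[1 : 1 + basis.n_baseline] = RNG.normal(size=basis.n_baseline)
        for b in (3.0, 14.0, 27.0):
            c = np.linspace(b - 27, b, 50)
            eta = basis.design(c, np.full(50, b)) @ theta
            assert np.ptp(eta) < 1e-10

    def test_random_nonnegative_tensor_draw_is_monotone_everywhere(self):
        basis = build_monotone_basis(SmoothSpec(), PHQ9)
        for _ in range(5):
            theta = RNG.normal(size=basis.n_coef)
            theta[basis.monotone_mask()] = np.abs(theta[basis.monotone_mask()])
            for b in range(0, 28):
                c = np.linspace(b - 27, b, 200)
                eta = basis.design(c, np.full(200, float(b))) @ theta
                assert np.diff(eta).min() >= -1e-9

    def test_too_few_basis_functions_rejected(self):
        with pytest.raises(ConfigurationError):
            SmoothSpec(n_basis_change=3)
        with pytest.raises(ConfigurationError):
            SmoothSpec(n_basis_change=4, penalty_order=3)

    def test_gcv_not_available(self):
        with pytest.raises(ConfigurationError, match="GCV"):
            SmoothSpec(smoothing_selection="GCV")


class TestFit:
    def test_flat_truth_recovers_half_everywhere(self):
        # outcome independent of covariates: the surface must stay near 0.5
        rng = np.random.default_rng(11)
        records = bernoulli_records(2000, lambda c, b: 0.5, rng)
        surface = fit_gamm(records)
        for b in range(1, 28):
            c = np.linspace(0, b, 30)
            p = surface.predict(c, float(b))
            assert np.all(np.abs(p - 0.5) <= 0.05)

    def test_monotonicity_contract_and_prediction_ordering(self, small_surface):
        assert small_surface.check_monotonicity(resolution=0.1)
        p1 = small_surface.predict(1.0, 15.0)
        p2 = small_surface.predict(6.0, 15.0)
        assert p1 <= p2
        assert 0.0 < p1 < 1.0 and 0.0 < p2 < 1.0

    def test_needs_both_outcome_classes(self):
        rng = np.random.default_rng(3)
        records = bernoulli_records(30, lambda c, b: 1.0, rng)
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_gamm(records)

    def test_unpenalized_fit_matches_statsmodels_logit(self):
        # with no random effect and negligible penalty the inner solver is
        # plain logistic MLE on the package's own design matrix
        # gentle slope keeps probabilities interior over the whole change
        # range, so the unpenalized MLE exists and is well conditioned
        rng = np.random.default_rng(5)
        records = bernoulli_records(3000, lambda c, b: 1 / (1 + np.exp(0.5 - 0.1 * c)), rng)
        spec = SmoothSpec(n_basis_change=4, n_basis_baseline=4)
        basis = build_monotone_basis(spec, PHQ9)
        y = np.array([1.0 if r.grc_binary == BETTER else 0.0 for r in records])
        change = np.array([r.change for r in records], float)
        baseline = np.array([r.baseline_score for r in records], float)
        g_center = basis.baseline_design(baseline).mean(axis=0)
        x = basis.design(change, baseline, g_center)
        # make the MLE identifiable: the centred baseline margin sums to zero
        # pointwise (partition of unity), so one of its columns is redundant,
        # and data-empty columns carry no information
        keep = np.abs(x).sum(axis=0) > 0
        keep[1] = False
        penalty = np.zeros((int(keep.sum()),) * 2)
        res = _solve_joint(x[:, keep], y, None, 0, penalty, 0.0, None)
        oracle = sm.Logit(y, x[:, keep]).fit(disp=0, method="newton", maxiter=200)
        assert res.success and oracle.mle_retvals["converged"]
        np.testing.assert_allclose(res.x, oracle.params, atol=1e-4)

    def test_laplace_likelihood_continuous_at_sigma_zero(self):
        # as sigma_u -> 0 the joint fit collapses to the independent logistic fit
        rng = np.random.default_rng(9)
        records = bernoulli_records(200, lambda c, b: 1 / (1 + np.exp(-0.3 * c)), rng, n_patients=50)
        spec = SmoothSpec(smoothing_selection="fixed", fixed_sigma_u=0.0)
        surf0 = fit_gamm(records, spec)
        surf_eps = fit_gamm(
            records, dataclasses.replace(spec, fixed_sigma_u=1e-4)
        )
        assert surf_eps.penalized_loglik == pytest.approx(surf0.penalized_loglik, abs=1e-3)
        np.testing.assert_allclose(surf_eps.theta, surf0.theta, atol=1e-3)

    def test_heavy_smoothing_flattens_to_linear(self, small_trial):
        # large penalties shrink the smooth toward its null space (linear trend)
        _, _, records = small_trial
        spec = SmoothSpec(
            smoothing_selection="fixed",
            lambda_surface=1e7,
            lambda_baseline=1e7,
            fixed_sigma_u=0.5,
        )
        surface = fit_gamm(records, spec)
        c = np.linspace(0, 14, 57)
        eta = surface.linear_predictor(c, np.full_like(c, 14.0))
        second_diff = np.diff(eta, n=2)
        assert np.abs(second_diff).max() < 1e-3

    def test_record_order_does_not_change_the_surface(self, small_trial):
        _, _, records = small_trial
        spec = SmoothSpec(smoothing_selection="fixed", fixed_sigma_u=0.5)
        surf_a = fit_gamm(records, spec)
        rng = np.random.default_rng(2)
        shuffled = list(records)
        rng.shuffle(shuffled)
        surf_b = fit_gamm(shuffled, spec)
        grid_c = np.linspace(0, 10, 21)
        pa = surf_a.predict(grid_c, 12.0)
        pb = surf_b.predict(grid_c, 12.0)
        np.testing.assert_allclose(pa, pb, atol=1e-6)


class TestPredict:
    def zero_surface(self):
        spec = SmoothSpec()
        basis = build_monotone_basis(spec, PHQ9)
        return MonotoneSurface(
            scale=PHQ9,
            spec=spec,
            intercept=0.0,
            gamma=np.zeros(basis.n_baseline),
            beta=np.zeros((basis.n_change, basis.n_baseline)),
            g_center=np.zeros(basis.n_baseline),
            lambda_surface=1.0,
            lambda_baseline=1.0,
            random_intercept_sd=0.0,
        )

    def test_all_zero_coefficients_predict_half(self):
        surface = self.zero_surface()
        assert surface.predict(0.0, 10.0) == pytest.approx(0.5)
        assert surface.predict(7.5, 12.0) == pytest.approx(0.5)
        grid = surface.predict(np.array([0.0, 3.0, 9.0]), 9.0)
        np.testing.assert_allclose(grid, 0.5)

    def test_out_of_domain_queries_rejected(self):
        surface = self.zero_surface()
        with pytest.raises(DomainError):
            surface.predict(5.0, 30.0)  # baseline beyond scale
        with pytest.raises(DomainError):
            surface.predict(15.0, 10.0)  # change larger than baseline
        with pytest.raises(DomainError):
            surface.predict(-26.0, 2.0)  # worse than scale-feasible deterioration

    def test_marginal_mode_shrinks_toward_half(self, small_surface):
        # averaging over random intercepts pulls extreme probabilities inward
        p_pop = small_surface.predict(10.0, 15.0)
        surface = dataclasses.replace(small_surface, random_intercept_sd=2.0)
        p_marg = surface.predict(10.0, 15.0, mode="marginal")
        assert abs(p_marg - 0.5) < abs(p_pop - 0.5)

    def test_serialization_roundtrip_preserves_predictions(self, small_surface):
        clone = MonotoneSurface.from_json(small_surface.to_json())
        c = np.linspace(0, 12, 25)
        np.testing.assert_allclose(
            clone.predict(c, 13.0), small_surface.predict(c, 13.0), atol=1e-12
        )
        assert clone.random_intercept_sd == small_surface.random_intercept_sd

    def test_module_level_wrapper_delegates(self, small_surface):
        assert predict_probability(small_surface, 4.0, 12.0) == pytest.approx(
            small_surface.predict(4.0, 12.0)
        )
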