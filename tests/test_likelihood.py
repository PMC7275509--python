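"""Forward log-likelihood, its gradient, and the multi-start fitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import approx_fprime

from movestates.containers import StepAngleSeries
from movestates.hmm import MovementHMM, forward_loglik, natural_to_working

from .conftest import make_series
from .oracles import (
    oracle_emission,
    oracle_loglik,
    random_observations,
    random_parameters,
)


class TestForwardLoglik:
    def test_single_step_closed_form(self):
        rng = np.random.default_rng(0)
        params = random_parameters(rng, K=2, p=1)
        steps, angles, design = random_observations(rng, T=1)
        series = make_series(steps, angles, design)
        expected = np.log(
            sum(
                params.delta[i] * oracle_emission(params, steps[0], angles[0], i)
                for i in range(2)
            )
        )
        assert np.isclose(forward_loglik(params, series), expected, atol=1e-10)

    @pytest.mark.parametrize("K,T,p", [(2, 4, 1), (3, 6, 2), (2, 8, 3), (3, 5, 1)])
    def test_matches_enumeration_oracle(self, K, T, p):
        rng = np.random.default_rng(K * 100 + T)
        for rep in range(5):
            params = random_parameters(rng, K, p, zero_mass=rep % 2 == 1)
            steps, angles, design = random_observations(
                rng, T, p, with_missing=rep >= 3
            )
            if rep % 2 == 1:
                steps[1] = 0.0
                angles[1] = np.nan
                if T > 2:
                    angles[2] = np.nan
            series = make_series(steps, angles, design)
            assert np.isclose(
                forward_loglik(params, series),
                oracle_loglik(params, steps, angles, design),
                atol=1e-8,
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        K=st.integers(2, 3),
        T=st.integers(2, 7),
    )
    def test_enumeration_property(self, seed, K, T):
        rng = np.random.default_rng(seed)
        params = random_parameters(rng, K, p=2)
        steps, angles, design = random_observations(rng, T, p=2)
        series = make_series(steps, angles, design)
        assert np.isclose(
            forward_loglik(params, series),
            oracle_loglik(params, steps, angles, design),
            atol=1e-8,
        )

    def test_all_missing_gives_zero(self):
        params = random_parameters(np.random.default_rng(1), K=3, p=1)
        series = make_series(
            np.full(5, np.nan), np.full(5, np.nan), np.ones((5, 1))
        )
        assert np.isclose(forward_loglik(params, series), 0.0, atol=1e-12)

    def test_bursts_add(self):
        rng = np.random.default_rng(2)
        params = random_parameters(rng, K=2, p=1)
        s1, a1, d1 = random_observations(rng, 6)
        s2, a2, d2 = random_observations(rng, 4)
        joint = StepAngleSeries(
            steps=np.concatenate([s1, s2]),
            angles=np.concatenate([a1, a2]),
            design=np.vstack([d1, d2]),
            lengths=np.array([6, 4]),
        )
        sep = forward_loglik(params, make_series(s1, a1, d1)) + forward_loglik(
            params, make_series(s2, a2, d2)
        )
        assert np.isclose(forward_loglik(params, joint), sep, atol=1e-9)

    def test_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(3)
        params = random_parameters(rng, K=3, p=2)
        steps, angles, design = random_observations(rng, 40, p=2)
        series = make_series(steps, angles, design)
        base = forward_loglik(params, series)
        for order in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            assert np.isclose(
                forward_loglik(params.permute(np.array(order)), series),
                base,
                atol=1e-9,
            )

    def test_empty_series_raises(self):
        params = random_parameters(np.random.default_rng(0), K=2)
        with pytest.raises(ValueError):
            forward_loglik(
                params,
                StepAngleSeries(
                    steps=np.empty(0),
                    angles=np.empty(0),
                    design=np.empty((0, 1)),
                    lengths=np.empty(0, int),
                ),
            )


class TestGradient:
    @pytest.mark.parametrize("zero_mass", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, zero_mass):
        rng = np.random.default_rng(4)
        steps, angles, design = random_observations(rng, 120, p=2, with_missing=True)
        if zero_mass:
            steps[np.array([5, 30])] = 0.0
            angles[np.array([5, 6, 30, 31])] = np.nan
        series = StepAngleSeries(
            steps=steps, angles=angles, design=design, lengths=np.array([60, 60])
        )
        model = MovementHMM(n_states=3)
        obj = model._make_objective(series, zero_mass)
        x0 = natural_to_working(
            random_parameters(rng, 3, 2, zero_mass=zero_mass), zero_mass
        )
        _, g = obj(x0)
        g_num = approx_fprime(x0, lambda x: obj(x)[0], 1e-7)
        assert np.allclose(g, g_num, atol=5e-3, rtol=1e-4)


class TestFit:
    def test_refit_same_seed_is_identical(self, small_series):
        series, _ = small_series
        a = MovementHMM(n_starts=2, random_state=42, compute_hessian=False).fit(series)
        b = MovementHMM(n_starts=2, random_state=42, compute_hessian=False).fit(series)
        assert a.log_likelihood_ == b.log_likelihood_
        assert np.array_equal(a.working_params_, b.working_params_)

    def test_states_ordered_by_step_mean(self, fitted_small):
        mu = fitted_small.params_.step_mean
        assert np.all(np.diff(mu) > 0)

    def test_bic_definition(self, fitted_small):
        m = fitted_small
        expected = -2 * m.log_likelihood_ + m.n_parameters_ * np.log(m.n_obs_)
        assert np.isclose(m.bic_, expected)

    def test_two_state_fit_separates_means(self):
        rng = np.random.default_rng(9)
        T = 2000
        states = (np.arange(T) // 50) % 2  # long alternating blocks
        steps = np.where(states == 0, rng.gamma(4, 5, T), rng.gamma(4, 100, T))
        angles = rng.vonmises(0.0, 1.0, T)
        angles[0] = np.nan
        series = make_series(steps, angles, np.ones((T, 1)))
        m = MovementHMM(
            n_states=2, n_starts=4, random_state=0, compute_hessian=False
        ).fit(series)
        assert m.params_.step_mean[0] < 100 < m.params_.step_mean[1]

    def test_fit_reports_start_diagnostics(self, fitted_small):
        m = fitted_small
        assert len(m.start_log_likelihoods_) == m.n_starts
        assert m.best_start_ == np.argmax(m.start_log_likelihoods_)
        assert m.converged_

    def test_covariance_is_symmetric_psd_ish(self, fitted_small):
        cov = fitted_small.covariance_
        assert cov is not None
        assert np.allclose(cov, cov.T, atol=1e-8)
        # diagonal gives usable standard errors
        assert np.all(np.diag(cov) > -1e-8)

    def test_estimator_standard_errors_shrink_with_data(self):
        from movestates.simulate import default_scenario, simulate_tracks, tracks_to_series

        ses = []
        for n_hours in (501, 2001):
            sc = default_scenario(n_animals=1, n_hours=n_hours, seed=5)
            series, _ = tracks_to_series(simulate_tracks(sc), sc)
            m = MovementHMM(n_starts=3, random_state=0).fit(series)
            ses.append(np.sqrt(np.clip(np.diag(m.covariance_), 0, None))[:6].mean())
        # quadrupling the data should roughly halve emission-parameter SEs
        assert ses[1] < 0.75 * ses[0]

    def test_k_below_two_rejected(self, small_series):
        series, _ = small_series
        with pytest.raises(ValueError):
            MovementHMM(n_states=1).fit(series)
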