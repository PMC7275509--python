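"""Viterbi decoding, stationary occupancy curves, CIs, pseudo-residuals."""

import numpy as np
import pandas as pd
import pytest

from movestates.containers import StepAngleSeries
from movestates.design import DesignEncoder
from movestates.hmm import MovementHMM
from movestates.inference import (
    mc_confidence_bands,
    pseudo_residuals,
    stationary_curve,
    stationary_distribution,
    von_mises_cdf,
)

from .conftest import make_series
from .oracles import (
    oracle_stationary,
    oracle_viterbi,
    random_observations,
    random_parameters,
)


def _model_from(params):
    """Wrap a parameter set in an unfitted-but-usable estimator shell."""
    m = MovementHMM(n_states=params.n_states)
    m.params_ = params
    m.estimate_zero_mass_ = bool(np.any(params.zero_mass > 0))
    m.covariance_ = None
    return m


class TestViterbi:
    @pytest.mark.parametrize("K,T", [(2, 5), (3, 6), (2, 8), (3, 4)])
    def test_matches_enumeration_argmax(self, K, T):
        rng = np.random.default_rng(K * 10 + T)
        for rep in range(5):
            params = random_parameters(rng, K, p=2)
            steps, angles, design = random_observations(rng, T, p=2)
            series = make_series(steps, angles, design)
            got = _model_from(params).predict(series) - 1
            assert np.array_equal(got, oracle_viterbi(params, steps, angles, design))

    def test_separated_emissions_recover_truth(self, small_series, fitted_small):
        series, truth = small_series
        acc = np.mean(fitted_small.predict(series) == truth)
        assert acc > 0.85

    def test_path_likelihood_bounded_by_total(self, small_series, fitted_small):
        from movestates.hmm import forward_loglik
        from .oracles import oracle_path_prob

        series, _ = small_series
        sub = StepAngleSeries(
            steps=series.steps[:10],
            angles=series.angles[:10],
            design=series.design[:10],
            lengths=np.array([10]),
        )
        path = fitted_small.predict(sub) - 1
        logp = np.log(
            oracle_path_prob(
                fitted_small.params_, sub.steps, sub.angles, sub.design, path
            )
        )
        assert logp <= forward_loglik(fitted_small.params_, sub) + 1e-9


class TestStationary:
    def test_symmetric_two_state(self):
        for p in (0.1, 0.4):
            G = np.array([[1 - p, p], [p, 1 - p]])
            assert np.allclose(stationary_distribution(G), [0.5, 0.5])

    def test_identical_rows_return_that_row(self):
        v = np.array([0.2, 0.5, 0.3])
        G = np.tile(v, (3, 1))
        assert np.allclose(stationary_distribution(G), v, atol=1e-12)

    def test_random_matrices_match_power_iteration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            G = rng.dirichlet(np.ones(3) * rng.uniform(0.5, 5), size=3)
            d = stationary_distribution(G)
            assert np.max(np.abs(d @ G - d)) < 1e-12
            assert np.allclose(d, oracle_stationary(G), atol=1e-8)

    def test_reducible_matrix_rejected(self):
        G = np.eye(3)
        with pytest.raises(ValueError):
            stationary_distribution(G)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.4], [0.5, 0.5]]))


@pytest.fixture(scope="module")
def curve_setup():
    """Fitted encoder + model shell with hand-set coefficients."""
    rng = np.random.default_rng(5)
    cov = pd.DataFrame(
        {
            "snow_depth": rng.uniform(0.0, 1.0, 500),
            "hour": np.tile(np.arange(24.0), 21)[:500],
        }
    )
    enc = DesignEncoder(
        {
            "snow_depth": {"kind": "continuous", "center": 0.5, "scale": 0.25},
            "hour": {"kind": "cyclic", "period": 24},
        }
    ).fit(cov)
    params = random_parameters(rng, K=3, p=4)
    return enc, _model_from(params), params


class TestStationaryCurve:
    def test_probabilities_sum_to_one(self, curve_setup):
        enc, model, _ = curve_setup
        curve = stationary_curve(
            model, enc, "snow_depth", np.linspace(0, 1, 11), context={"hour": 12}
        )
        assert np.allclose(curve.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_slopes_give_flat_curve(self, curve_setup):
        enc, model, params = curve_setup
        flat = params.permute(np.array([0, 1, 2]))  # copy
        flat.beta[1, :] = 0.0  # snow_depth design column
        curve = stationary_curve(
            _model_from(flat), enc, "snow_depth", np.linspace(0, 1, 7),
            context={"hour": 12},
        )
        assert np.allclose(curve.probs, curve.probs[0], atol=1e-12)

    def test_single_pair_slope_is_monotone(self, curve_setup):
        enc, model, params = curve_setup
        mono = params.permute(np.array([0, 1, 2]))
        mono.beta[:, :] = 0.0
        mono.beta[0, :] = -1.0
        mono.beta[1, 0] = 2.0  # only resting->foraging responds to snow
        curve = stationary_curve(
            _model_from(mono), enc, "snow_depth", np.linspace(0, 1, 41),
            context={"hour": 12},
        )
        forage = curve.probs[:, 1]
        assert np.all(np.diff(forage) > 0)

    def test_out_of_range_grid_warns(self, curve_setup):
        enc, model, _ = curve_setup
        with pytest.warns(UserWarning, match="observed range"):
            stationary_curve(
                model, enc, "snow_depth", [2.0], context={"hour": 12},
                observed_range=(0.0, 1.0),
            )

    def test_unknown_covariate_raises(self, curve_setup):
        enc, model, _ = curve_setup
        with pytest.raises(ValueError):
            stationary_curve(model, enc, "ndvi", [0.0])


class TestConfidenceBands:
    def test_zero_covariance_collapses_bands(self, curve_setup):
        enc, model, params = curve_setup
        from movestates.hmm import natural_to_working

        model.working_params_ = natural_to_working(params, False)
        model.covariance_ = np.zeros(
            (model.working_params_.size, model.working_params_.size)
        )
        curve = mc_confidence_bands(
            model, enc, "snow_depth", np.linspace(0, 1, 5),
            context={"hour": 12}, n_draws=50, seed=0,
        )
        assert np.allclose(curve.lower, curve.probs, atol=1e-12)
        assert np.allclose(curve.upper, curve.probs, atol=1e-12)

    def test_deterministic_under_seed_and_ordered(self, fitted_small, small_scenario):
        from movestates.simulate import simulate_covariates

        enc = small_scenario.encoder().fit(
            simulate_covariates(small_scenario)
        )
        grid = np.linspace(0.1, 0.6, 6)
        a = mc_confidence_bands(
            fitted_small, enc, "snow_depth", grid, context={"hour": 12},
            n_draws=200, seed=3,
        )
        b = mc_confidence_bands(
            fitted_small, enc, "snow_depth", grid, context={"hour": 12},
            n_draws=200, seed=3,
        )
        assert np.array_equal(a.lower, b.lower)
        assert np.all(a.lower <= a.probs + 1e-12)
        assert np.all(a.probs <= a.upper + 1e-12)
        assert np.any(a.upper - a.lower > 1e-4)

    def test_band_width_stable_in_draw_count(self, fitted_small, small_scenario):
        from movestates.simulate import simulate_covariates

        enc = small_scenario.encoder().fit(simulate_covariates(small_scenario))
        grid = np.linspace(0.2, 0.5, 4)
        a = mc_confidence_bands(
            fitted_small, enc, "snow_depth", grid, context={"hour": 12},
            n_draws=400, seed=1,
        )
        b = mc_confidence_bands(
            fitted_small, enc, "snow_depth", grid, context={"hour": 12},
            n_draws=800, seed=2,
        )
        assert np.max(np.abs(a.lower - b.lower)) < 0.05
        assert np.max(np.abs(a.upper - b.upper)) < 0.05


class TestVonMisesCdf:
    def test_matches_quadrature(self):
        from scipy import integrate

        from movestates.hmm import angle_density

        for phi, kap in [(0.0, 0.5), (1.2, 3.0), (-2.0, 8.0)]:
            for theta in (-2.0, 0.0, 1.5, np.pi):
                num, _ = integrate.quad(
                    lambda t: angle_density(t, phi, kap), -np.pi, theta
                )
                assert np.isclose(
                    von_mises_cdf(theta, phi, kap), num, atol=1e-8
                ), (phi, kap, theta)

    def test_endpoints(self):
        assert np.isclose(von_mises_cdf(-np.pi, 0.3, 2.0), 0.0, atol=1e-10)
        assert np.isclose(von_mises_cdf(np.pi, 0.3, 2.0), 1.0, atol=1e-10)


class TestPseudoResiduals:
    def test_well_specified_model_gives_normal_residuals(
        self, small_series, fitted_small
    ):
        from scipy import stats

        series, _ = small_series
        res = pseudo_residuals(fitted_small, series)
        for col in ("step_residual", "angle_residual"):
            r = res[col].dropna()
            assert abs(r.mean()) < 0.08
            assert abs(r.std() - 1.0) < 0.08
            # gross distributional check; exact normality is asymptotic
            ks = stats.kstest(r, "norm").statistic
            assert ks < 0.05, col

    def test_misspecified_model_deviates(self, small_series, fitted_small):
        from scipy import stats

        series, _ = small_series
        good = fitted_small.params_
        bad_params = good.permute(np.array([0, 1, 2]))  # deep copy
        bad_params.step_mean = good.step_mean * np.array([1.0, 3.0, 1.0])
        bad = _model_from(bad_params)
        ks_good = stats.kstest(
            pseudo_residuals(fitted_small, series)["step_residual"].dropna(),
            "norm",
        ).statistic
        ks_bad = stats.kstest(
            pseudo_residuals(bad, series)["step_residual"].dropna(), "norm"
        ).statistic
        assert ks_bad > 0.1 > ks_good

    def test_all_missing_series_gives_all_missing_residuals(self, fitted_small):
        series = StepAngleSeries(
            steps=np.full(6, np.nan),
            angles=np.full(6, np.nan),
            design=np.column_stack(
                [np.ones(6), np.zeros((6, 3))]
            ),
            lengths=np.array([6]),
        )
        res = pseudo_residuals(fitted_small, series)
        assert res["step_residual"].isna().all()
        assert res["angle_residual"].isna().all()
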