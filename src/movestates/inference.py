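"""Decoding and characterisation of a fitted movement HMM.

* Viterbi decoding of the most likely behavioural state sequence,
* covariate-conditional stationary state-occupancy curves (the long-run
  probability of each state if the chain ran forever at fixed covariate
  values) with Monte Carlo confidence bands drawn from the estimator's
  approximate multivariate normal distribution,
* one-step-ahead pseudo-residuals for goodness-of-fit checks.

The stationary treatment of a time-varying chain is an approximation:
delta(Gamma(x)) summarises occupancy "at covariate value x" even though
the realised chain never sits still at one x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import _kernels
from .containers import StepAngleSeries
from .design import DesignEncoder
from .hmm import MovementHMM, _logb_eta, gamma_shape_rate

__all__ = [
    "viterbi",
    "stationary_distribution",
    "StationaryCurve",
    "stationary_curve",
    "mc_confidence_bands",
    "pseudo_residuals",
    "von_mises_cdf",
]


def viterbi(model: MovementHMM, series: StepAngleSeries) -> np.ndarray:
    """Most likely state sequence (1-based, per burst) for the series."""
    return model.predict(series)


def stationary_distribution(gamma: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Solve delta Gamma = delta, sum(delta) = 1 for a row-stochastic Gamma.

    Uses the augmented linear system delta (I - Gamma + U) = 1 with U the
    all-ones matrix.  Raises on matrices that are reducible or periodic
    within tolerance (no unique strictly positive solution).
    """
    G = np.asarray(gamma, float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("transition matrix must be square")
    K = G.shape[0]
    if not np.allclose(G.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    A = np.eye(K) - G.T + np.ones((K, K))
    try:
        delta = np.linalg.solve(A, np.ones(K))
    except np.linalg.LinAlgError as exc:
        raise ValueError("transition matrix has no unique stationary law") from exc
    if np.any(delta < -tol) or abs(delta.sum() - 1.0) > 1e-8:
        raise ValueError("transition matrix appears reducible or periodic")
    resid = np.max(np.abs(delta @ G - delta))
    if resid > 1e-8:
        raise ValueError(f"stationary solve residual too large: {resid:.2e}")
    return np.clip(delta, 0.0, None) / np.clip(delta, 0.0, None).sum()


@dataclass
class StationaryCurve:
    """Per-state stationary occupancy along one covariate's grid."""

    covariate: str
    grid: np.ndarray
    probs: np.ndarray  # (n_grid, K)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    context: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        K = self.probs.shape[1]
        rows = []
        for g in range(len(self.grid)):
            for k in range(K):
                rows.append(
                    {
                        "covariate": self.covariate,
                        "value": self.grid[g],
                        "state": k + 1,
                        "estimate": self.probs[g, k],
                        "lo95": np.nan if self.lower is None else self.lower[g, k],
                        "hi95": np.nan if self.upper is None else self.upper[g, k],
                    }
                )
        return pd.DataFrame(rows)


def _context_frame(
    encoder: DesignEncoder, covariate: str, grid: np.ndarray, context: dict
) -> pd.DataFrame:
    """One covariate row per grid value, the rest at fixed context values.

    Continuous covariates default to their seasonal mean (the encoder's
    centring constant), categorical covariates to their reference level;
    cyclic covariates must be fixed explicitly (e.g. hour 12) unless they
    are the target.
    """
    specs = encoder._specs()
    if covariate not in specs:
        raise ValueError(f"{covariate!r} is not part of the fitted design")
    data = {}
    for name, sp in specs.items():
        if name == covariate:
            data[name] = grid
        elif name in context:
            data[name] = [context[name]] * len(grid)
        elif sp.kind == "continuous":
            data[name] = [encoder.center_[name]] * len(grid)
        elif sp.kind == "categorical":
            data[name] = [sp.reference] * len(grid)
        else:
            raise ValueError(
                f"cyclic covariate {name!r} needs an explicit context value"
            )
    return pd.DataFrame(data)


def _curve_probs(beta: np.ndarray, design: np.ndarray) -> np.ndarray:
    G = _kernels.build_transition_matrices(beta, design)
    return np.stack([stationary_distribution(G[t]) for t in range(G.shape[0])])


def stationary_curve(
    model: MovementHMM,
    encoder: DesignEncoder,
    covariate: str,
    grid,
    context: dict | None = None,
    observed_range: tuple[float, float] | None = None,
) -> StationaryCurve:
    """Stationary state occupancy as a function of one covariate.

    All other continuous covariates sit at their seasonal means and
    categorical covariates at their reference categories (overridable
    through ``context``); for each grid value the implied transition
    matrix is solved for its stationary distribution.
    """
    grid = np.asarray(grid, float)
    context = dict(context or {})
    if observed_range is not None and (
        grid.min() < observed_range[0] or grid.max() > observed_range[1]
    ):
        warnings.warn(
            f"grid for {covariate!r} extends outside the observed range "
            f"{observed_range}", stacklevel=2,
        )
    frame = _context_frame(encoder, covariate, grid, context)
    design = encoder.transform(frame)
    probs = _curve_probs(model.params_.beta, design)
    return StationaryCurve(
        covariate=covariate, grid=grid, probs=probs, context=context
    )


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.all(w >= 0):
        return cov
    warnings.warn(
        "estimator covariance not positive semi-definite; clipping negative "
        "eigenvalues", stacklevel=3,
    )
    return (v * np.clip(w, 0.0, None)) @ v.T


def mc_confidence_bands(
    model: MovementHMM,
    encoder: DesignEncoder,
    covariate: str,
    grid,
    context: dict | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> StationaryCurve:
    """Pointwise Monte Carlo confidence bands for a stationary curve.

    Parameter vectors are drawn from the estimator's approximate
    multivariate normal distribution (mean = estimate, covariance =
    inverse observed information, marginalised to the transition
    coefficients the curve depends on); the curve is recomputed per draw
    and pointwise 2.5/97.5 percentiles are taken.
    """
    if model.covariance_ is None:
        raise ValueError("model has no estimator covariance; refit with the Hessian")
    curve = stationary_curve(model, encoder, covariate, grid, context)
    frame = _context_frame(encoder, covariate, curve.grid, dict(context or {}))
    design = encoder.transform(frame)

    # the curve depends on the transition coefficients only, so draw from
    # their marginal normal (the trailing block of the working vector);
    # this keeps weakly identified nuisance blocks (e.g. the initial
    # distribution) from contaminating the draws
    K = model.params_.n_states
    beta_hat = model.params_.beta
    n_beta = beta_hat.size
    cov_beta = _nearest_psd(np.asarray(model.covariance_)[-n_beta:, -n_beta:])
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        beta_hat.ravel(), cov_beta, size=n_draws, method="eigh"
    )
    sims = np.empty((n_draws, len(curve.grid), K))
    for d in range(n_draws):
        try:
            sims[d] = _curve_probs(draws[d].reshape(beta_hat.shape), design)
        except ValueError:
            sims[d] = np.nan
    alpha = (1.0 - level) / 2.0
    lower = np.nanpercentile(sims, 100 * alpha, axis=0)
    upper = np.nanpercentile(sims, 100 * (1 - alpha), axis=0)
    curve.lower = np.minimum(lower, curve.probs)
    curve.upper = np.maximum(upper, curve.probs)
    return curve


def von_mises_cdf(theta, mean: float, concentration: float) -> np.ndarray:
    """Von Mises CDF on (-pi, pi], anchored at -pi, via a Bessel series."""
    theta = np.asarray(theta, float)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    out = (theta + np.pi) / (2.0 * np.pi)
    i0e = special.i0e(concentration)
    acc = np.zeros_like(out)
    for j in range(1, 300):
        r = special.ive(j, concentration) / i0e
        if r / j < 1e-14:
            break
        acc += r / j * (
            np.sin(j * (theta - mean)) + np.sin(j * (np.pi + mean))
        )
    return np.clip(out + acc / np.pi, 0.0, 1.0)


def pseudo_residuals(model: MovementHMM, series: StepAngleSeries) -> pd.DataFrame:
    """One-step-ahead probability-integral-transform residuals.

    The forecast CDF of each observation given all earlier observations
    of its burst is mixed over states with the forward prediction
    weights and mapped through the standard normal quantile function.
    Under a correctly specified model the residuals are approximately
    iid standard normal; missing observations yield missing residuals.
    An exact zero step (a discrete atom) is assigned its mid-probability.
    """
    params = model.params_
    logb, eta = _logb_eta(params, series)
    _, pred = _kernels.forward_normalised(logb, eta, params.delta, series.lengths)
    K = params.n_states
    shape, rate = gamma_shape_rate(params.step_mean, params.step_sd)

    steps, angles = series.steps, series.angles
    T = series.n_steps
    u_step = np.full(T, np.nan)
    ok = np.isfinite(steps)
    pos = ok & (steps > 0)
    zero = ok & (steps == 0)
    F = np.zeros((T, K))
    for i in range(K):
        F[pos, i] = params.zero_mass[i] + (1 - params.zero_mass[i]) * stats.gamma.cdf(
            steps[pos], a=shape[i], scale=1.0 / rate[i]
        )
        F[zero, i] = 0.5 * params.zero_mass[i]  # mid-p for the atom at zero
    u_step[ok] = np.sum(pred[ok] * F[ok], axis=1)

    u_ang = np.full(T, np.nan)
    oka = np.isfinite(angles)
    Fa = np.zeros((T, K))
    for i in range(K):
        Fa[oka, i] = von_mises_cdf(
            angles[oka], params.angle_mean[i], params.angle_conc[i]
        )
    u_ang[oka] = np.sum(pred[oka] * Fa[oka], axis=1)

    eps = 1e-12
    for u in (u_step, u_ang):
        clipped = (u < eps) | (u > 1 - eps)
        if np.any(clipped[np.isfinite(u)]):
            warnings.warn("pseudo-residual CDF values clamped away from 0/1",
                          stacklevel=2)
        np.clip(u, eps, 1 - eps, out=u)

    burst_ids = np.repeat(np.arange(series.n_bursts), series.lengths)
    return pd.DataFrame(
        {
            "burst": burst_ids,
            "step_residual": stats.norm.ppf(u_step),
            "angle_residual": stats.norm.ppf(u_ang),
            "step_uniform": u_step,
            "angle_uniform": u_ang,
        }
    )
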