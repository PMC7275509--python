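"""Bivariate movement HMM: emissions, likelihood, and multi-start fitting.

The model: an animal's hourly step lengths and turning angles are driven
by a K-state latent Markov chain.  Conditional on state i, step lengths
are gamma(mean mu_i, sd sigma_i) with an optional point mass zeta_i at
exactly zero, and turning angles are von Mises(phi_i, kappa_i).  Each row
of the transition matrix follows a multinomial logit in per-step
covariates, with the self-transition as reference category:

    eta_ij(t) = z_t' beta_(i->j)   (j != i),   eta_ii = 0
    Gamma_ij(t) = exp(eta_ij(t)) / sum_k exp(eta_ik(t))

Estimation is direct numerical maximisation of the scaled forward
log-likelihood on an unconstrained working scale, repeated from multiple
random starting values to guard against local maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from . import _kernels
from .containers import HMMParameters, StepAngleSeries, transition_pairs

__all__ = [
    "MovementHMM",
    "HMMFitError",
    "step_density",
    "angle_density",
    "gamma_shape_rate",
    "build_transition_matrices",
    "forward_loglik",
    "moment_start",
    "natural_to_working",
    "working_to_natural",
    "fit_hmm",
]

build_transition_matrices = _kernels.build_transition_matrices


class HMMFitError(RuntimeError):
    """Raised when no optimisation start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# state-dependent densities
# ---------------------------------------------------------------------------

def gamma_shape_rate(mean, sd):
    """Convert the mean/sd gamma parameterisation to (shape, rate).

    shape = mean^2 / sd^2, rate = mean / sd^2; exactly invertible via
    mean = shape/rate, sd = sqrt(shape)/rate.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    if np.any(mean <= 0) or np.any(sd <= 0):
        raise ValueError("step mean and sd must be positive")
    return mean**2 / sd**2, mean / sd**2


def step_density(length, mean, sd, zero_mass=0.0):
    """Gamma step-length density with optional point mass at zero.

    For length > 0 returns (1 - zero_mass) * Gamma(length; shape, rate);
    at exactly 0 returns the point probability zero_mass.
    """
    length = np.asarray(length, float)
    if np.any(length < 0):
        raise ValueError("step lengths must be non-negative")
    shape, rate = gamma_shape_rate(mean, sd)
    dens = (1.0 - zero_mass) * stats.gamma.pdf(length, a=shape, scale=1.0 / rate)
    return np.where(length == 0.0, zero_mass, dens)


def angle_density(angle, mean, concentration):
    """Von Mises turning-angle density exp(k cos(a - m)) / (2 pi I0(k))."""
    angle = np.asarray(angle, float)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    # i0e keeps this finite for large concentrations
    return np.exp(concentration * (np.cos(angle - mean) - 1.0)) / (
        2.0 * np.pi * special.i0e(concentration)
    )


def _emission_constants(params: HMMParameters):
    shape, rate = gamma_shape_rate(params.step_mean, params.step_sd)
    lg = special.gammaln(shape)
    kappa = params.angle_conc
    log_norm_vm = np.log(2.0 * np.pi * special.i0e(kappa)) + kappa
    return shape, rate, lg, log_norm_vm


def _logb_eta(params: HMMParameters, series: StepAngleSeries):
    shape, rate, lg, log_norm_vm = _emission_constants(params)
    logb = _kernels.emission_logdens(
        series.steps,
        series.angles,
        shape,
        rate,
        lg,
        params.zero_mass,
        params.angle_mean,
        params.angle_conc,
        log_norm_vm,
    )
    eta = series.design @ params.beta
    return logb, eta


def forward_loglik(params: HMMParameters, series: StepAngleSeries) -> float:
    """Total scaled-forward log-likelihood over all bursts.

    Missing step/angle components contribute emission factor 1; a fully
    missing observation therefore only propagates the chain.
    """
    if series.n_steps == 0:
        raise ValueError("empty series")
    if series.design.shape[1] != params.n_design:
        raise ValueError(
            f"design has {series.design.shape[1]} columns, "
            f"beta expects {params.n_design}"
        )
    logb, eta = _logb_eta(params, series)
    if not np.all(np.isfinite(logb[logb > -1e299])):
        raise FloatingPointError("non-finite emission densities")
    return float(_kernels.forward_logsum(logb, eta, params.delta, series.lengths))


# ---------------------------------------------------------------------------
# working-scale transforms
# ---------------------------------------------------------------------------

def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    w = np.mod(-np.asarray(a, float) + np.pi, 2.0 * np.pi)
    return -(w - np.pi)


def natural_to_working(params: HMMParameters, estimate_zero_mass: bool) -> np.ndarray:
    """Pack natural parameters into the unconstrained working vector.

    Layout: log mu (K) | log sigma (K) | [logit zeta (K)] | phi (K) |
    log kappa (K) | delta logits vs state 1 (K-1) | beta.ravel() (C order).
    """
    parts = [np.log(params.step_mean), np.log(params.step_sd)]
    if estimate_zero_mass:
        z = params.zero_mass
        if np.any(z <= 0) or np.any(z >= 1):
            raise ValueError("zero_mass must be in (0,1) when estimated")
        parts.append(special.logit(z))
    parts.append(params.angle_mean.copy())
    parts.append(np.log(params.angle_conc))
    d = params.delta
    if np.any(d <= 0):
        raise ValueError("delta must be strictly positive on the working scale")
    parts.append(np.log(d[1:] / d[0]))
    parts.append(params.beta.ravel())
    return np.concatenate(parts)


def working_to_natural(
    vec: np.ndarray, n_states: int, n_design: int, estimate_zero_mass: bool
) -> HMMParameters:
    """Inverse of :func:`natural_to_working`; wraps angle means into (-pi, pi]."""
    K = n_states
    vec = np.asarray(vec, float)
    if not np.all(np.isfinite(vec)) or np.any(np.abs(vec) > 500.0):
        raise ValueError("working vector out of the numerically safe range")
    pos = 0

    def take(n):
        nonlocal pos
        out = vec[pos : pos + n]
        pos += n
        return out

    mu = np.exp(take(K))
    sigma = np.exp(take(K))
    zeta = special.expit(take(K)) if estimate_zero_mass else np.zeros(K)
    phi = _wrap_angle(take(K))
    kappa = np.exp(take(K))
    dl = np.concatenate([[0.0], take(K - 1)])
    dl -= dl.max()
    delta = np.exp(dl)
    delta /= delta.sum()
    beta = take(n_design * K * (K - 1)).reshape(n_design, K * (K - 1))
    if pos != vec.size:
        raise ValueError(f"working vector has wrong length {vec.size}, expected {pos}")
    return HMMParameters(
        step_mean=mu,
        step_sd=sigma,
        zero_mass=zeta,
        angle_mean=phi,
        angle_conc=kappa,
        beta=beta,
        delta=delta,
    )


def _gradient_hessian(grad, x, h=1e-5):
    """Hessian by central differences of an analytic gradient, symmetrised."""
    n = x.size
    H = np.empty((n, n))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = hs[i]
        H[i] = (grad(x + ei) - grad(x - ei)) / (2 * hs[i])
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

@dataclass
class _StartResult:
    loglik: float
    x: np.ndarray
    success: bool
    message: str


class MovementHMM(BaseEstimator):
    """K-state bivariate HMM for step lengths and turning angles.

    Follows the scikit-learn estimator protocol; sequences are passed
    either as a :class:`StepAngleSeries` or as a 2-D array with columns
    ``[step, angle, design...]`` plus a ``lengths`` vector (hmmlearn
    style).  States are relabelled after fitting by ascending step-length
    mean, so with the default three states 1 = resting, 2 = foraging,
    3 = relocating; ``predict`` returns these 1-based labels.

    Parameters
    ----------
    n_states : int, default 3
        Number of latent behavioural states (>= 2).
    n_starts : int, default 30
        Independent optimisations from random starting values; the best
        log-likelihood wins.
    estimate_zero_mass : {"auto", True, False}
        Whether to estimate a point mass at zero step length.  "auto"
        estimates it only when the data contain exact zeros (otherwise it
        is fixed at 0 and excluded from the parameter count).
    stationary_start : bool, default False
        If True the initial state distribution is the stationary
        distribution of Gamma at each burst's first design row instead of
        a free parameter.
    compute_hessian : bool, default True
        Compute the observed information and estimator covariance at the
        optimum (skipped during cheap model-selection rounds).
    max_iter : int
        Iteration cap per optimisation start (L-BFGS on the working scale,
        finite-difference gradients).
    tol : float
        Relative function tolerance of the optimiser.
    random_state : int or None
        Seed for the start-value generator; fits are deterministic given
        the seed and data.
    initial_params : list of working vectors or None
        Optional warm starts used before random starts are drawn (counted
        against ``n_starts``); model selection uses this to seed candidate
        fits from the incumbent model.
    """

    def __init__(
        self,
        n_states: int = 3,
        n_starts: int = 30,
        estimate_zero_mass="auto",
        stationary_start: bool = False,
        compute_hessian: bool = True,
        max_iter: int = 500,
        tol: float = 1e-10,
        random_state: int | None = None,
        initial_params: list | None = None,
    ):
        self.n_states = n_states
        self.n_starts = n_starts
        self.estimate_zero_mass = estimate_zero_mass
        self.stationary_start = stationary_start
        self.compute_hessian = compute_hessian
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.initial_params = initial_params

    # -- data plumbing ------------------------------------------------------

    @staticmethod
    def _as_series(X, lengths=None) -> StepAngleSeries:
        if isinstance(X, StepAngleSeries):
            return X
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] < 3:
            raise ValueError(
                "array input needs columns [step, angle, intercept, ...covariates]"
            )
        if lengths is None:
            lengths = np.array([X.shape[0]])
        return StepAngleSeries(
            steps=X[:, 0], angles=X[:, 1], design=X[:, 2:], lengths=lengths
        )

    # -- objective ----------------------------------------------------------

    def _make_objective(self, series: StepAngleSeries, estimate_zero: bool):
        """Negative log-likelihood with its analytic gradient.

        The gradient uses the forward-backward adjoint: smoothed state
        posteriors weight the per-observation emission score functions, and
        transition-pair adjoints chain through the design matrix into the
        multinomial-logit coefficients.
        """
        K = int(self.n_states)
        p = series.design.shape[1]
        steps, angles = series.steps, series.angles
        design, lengths = series.design, series.lengths
        stationary = bool(self.stationary_start)
        n = p * K * (K - 1) + K * (4 + estimate_zero) + K - 1

        mask_pos = np.isfinite(steps) & (steps > 0)
        mask_zero = steps == 0.0
        mask_ang = np.isfinite(angles)
        log_steps = np.where(mask_pos, np.log(np.where(mask_pos, steps, 1.0)), 0.0)

        def objective(x):
            bad = np.inf, np.zeros(n)
            try:
                params = working_to_natural(x, K, p, estimate_zero)
            except (ValueError, FloatingPointError):
                return bad
            with np.errstate(over="ignore", invalid="ignore"):
                shape, rate, lg, log_norm_vm = _emission_constants(params)
                if not (np.all(np.isfinite(shape)) and np.all(np.isfinite(rate))):
                    return bad
                # the continuous likelihood is unbounded when a state
                # degenerates onto single observations (sigma -> 0 with
                # shape -> inf, or kappa -> inf); cap both far beyond any
                # biologically meaningful value
                if np.any(shape > 1e6) or np.any(params.angle_conc > 1e4):
                    return bad
                logb = _kernels.emission_logdens(
                    steps, angles, shape, rate, lg, params.zero_mass,
                    params.angle_mean, params.angle_conc, log_norm_vm,
                )
                eta = design @ params.beta
                if not np.all(np.isfinite(eta)):
                    return bad
                delta = params.delta
                if stationary:
                    from .inference import stationary_distribution

                    G0 = build_transition_matrices(params.beta, design[:1])[0]
                    try:
                        delta = stationary_distribution(G0)
                    except Exception:
                        return bad
                ll, gamma, omega, gdelta = _kernels.forward_backward_grad(
                    logb, eta, delta, lengths
                )
                if not np.isfinite(ll):
                    return bad
                grad = np.empty(n)
                pos = 0
                zeta, phi, kappa = params.zero_mass, params.angle_mean, params.angle_conc
                a_ratio = special.i1e(kappa) / special.i0e(kappa)
                digam = special.digamma(shape)
                g_mu = np.empty(K)
                g_sg = np.empty(K)
                g_ze = np.empty(K)
                g_ph = np.empty(K)
                g_ka = np.empty(K)
                for i in range(K):
                    w = gamma[:, i]
                    ws = w[mask_pos]
                    core = np.log(rate[i]) - digam[i] + log_steps[mask_pos]
                    amrl = shape[i] - rate[i] * steps[mask_pos]
                    g_mu[i] = np.sum(ws * (2.0 * shape[i] * core + amrl))
                    g_sg[i] = np.sum(ws * (-2.0 * shape[i] * core - 2.0 * amrl))
                    if estimate_zero:
                        g_ze[i] = (1.0 - zeta[i]) * np.sum(w[mask_zero]) - zeta[
                            i
                        ] * np.sum(ws)
                    d = angles[mask_ang] - phi[i]
                    wa = w[mask_ang]
                    g_ph[i] = np.sum(wa * kappa[i] * np.sin(d))
                    g_ka[i] = np.sum(wa * kappa[i] * (np.cos(d) - a_ratio[i]))
                grad[pos : pos + K] = g_mu
                pos += K
                grad[pos : pos + K] = g_sg
                pos += K
                if estimate_zero:
                    grad[pos : pos + K] = g_ze
                    pos += K
                grad[pos : pos + K] = g_ph
                pos += K
                grad[pos : pos + K] = g_ka
                pos += K
                grad[pos : pos + K - 1] = gdelta[1:] if not stationary else 0.0
                pos += K - 1
                grad[pos:] = (design.T @ omega).ravel()
            if not np.all(np.isfinite(grad)):
                return bad
            return -ll, -grad

        return objective

    def _random_start(self, rng, series: StepAngleSeries, estimate_zero: bool):
        """Random start scheme: ordered log-uniform step means between the
        10th and 90th percentile of positive observed steps (sd = mean),
        log-uniform concentrations, angle means at 0 or pi, sticky
        transition intercepts, zero covariate slopes."""
        K = int(self.n_states)
        p = series.design.shape[1]
        pos = series.steps[np.isfinite(series.steps) & (series.steps > 0)]
        if pos.size < K:
            raise ValueError("not enough positive steps to initialise")
        lo, hi = np.quantile(pos, [0.10, 0.90])
        lo = max(lo, 1e-6)
        hi = max(hi, lo * (1 + 1e-6))
        mu = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), K)))
        sigma = mu.copy()
        kappa = np.exp(rng.uniform(np.log(0.1), np.log(5.0), K))
        phi = rng.choice([0.0, np.pi], size=K)
        beta = np.zeros((p, K * (K - 1)))
        beta[0] = rng.normal(-2.0, 0.5, K * (K - 1))
        zeta = np.full(K, 0.05) if estimate_zero else np.zeros(K)
        params = HMMParameters(
            step_mean=mu,
            step_sd=sigma,
            zero_mass=zeta if estimate_zero else None,
            angle_mean=phi,
            angle_conc=kappa,
            beta=beta,
            delta=np.full(K, 1.0 / K),
        )
        return natural_to_working(params, estimate_zero)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, lengths=None):
        """Fit by multi-start maximum likelihood.

        Parameters
        ----------
        X : StepAngleSeries or (T, 2+p) array
        lengths : (n_bursts,) array, required for array input with several
            bursts
        """
        series = self._as_series(X, lengths)
        K = int(self.n_states)
        if K < 2:
            raise ValueError("n_states must be >= 2")
        if series.n_steps == 0:
            raise ValueError("empty series")
        if self.estimate_zero_mass == "auto":
            estimate_zero = bool(np.any(series.steps == 0.0))
        else:
            estimate_zero = bool(self.estimate_zero_mass)
        rng = np.random.default_rng(self.random_state)
        objective = self._make_objective(series, estimate_zero)

        warm = [np.asarray(v, float) for v in (self.initial_params or [])]
        results: list[_StartResult] = []
        for k in range(int(self.n_starts)):
            if k < len(warm):
                x0 = warm[k]
            else:
                x0 = self._random_start(rng, series, estimate_zero)
            try:
                res = optimize.minimize(
                    objective,
                    x0,
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": self.max_iter, "ftol": self.tol},
                )
                if np.isfinite(res.fun):
                    # restart with fresh curvature memory: L-BFGS occasionally
                    # declares convergence on a likelihood plateau
                    res2 = optimize.minimize(
                        objective,
                        res.x,
                        jac=True,
                        method="L-BFGS-B",
                        options={"maxiter": self.max_iter, "ftol": self.tol},
                    )
                    if res2.fun <= res.fun:
                        res = res2
                results.append(
                    _StartResult(-res.fun, res.x, bool(res.success), res.message)
                )
            except FloatingPointError as exc:  # pragma: no cover - defensive
                results.append(_StartResult(-np.inf, x0, False, str(exc)))
        ok = [r for r in results if np.isfinite(r.loglik)]
        if not ok:
            raise HMMFitError(
                "all optimisation starts failed",
                diagnostics=[(r.loglik, r.message) for r in results],
            )
        best_i = int(np.argmax([r.loglik if np.isfinite(r.loglik) else -np.inf
                                for r in results]))
        best = results[best_i]

        p = series.design.shape[1]
        params = working_to_natural(best.x, K, p, estimate_zero)
        # relabel ascending step mean: resting < foraging < relocating
        order = np.argsort(params.step_mean, kind="stable")
        params = params.permute(order)
        x_best = natural_to_working(params, estimate_zero)

        self.estimate_zero_mass_ = estimate_zero
        self.params_ = params
        self.working_params_ = x_best
        self.log_likelihood_ = float(best.loglik)
        self.n_parameters_ = int(x_best.size)
        self.n_obs_ = series.n_obs
        self.bic_ = -2.0 * self.log_likelihood_ + self.n_parameters_ * math.log(
            self.n_obs_
        )
        self.start_log_likelihoods_ = np.array([r.loglik for r in results])
        self.best_start_ = best_i
        self.converged_ = bool(best.success)
        self.feature_names_in_ = list(series.feature_names)
        self.n_features_in_ = p

        self.covariance_ = None
        if self.compute_hessian:
            H = _gradient_hessian(lambda x: objective(x)[1], x_best)
            if np.all(np.isfinite(H)):
                try:
                    cov = np.linalg.pinv(H)
                except np.linalg.LinAlgError:  # pragma: no cover
                    cov = None
                self.covariance_ = cov
                self.information_ = H
            else:
                self.converged_ = False
        return self

    # -- inference ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def score(self, X, y=None, lengths=None) -> float:
        """Total log-likelihood of X under the fitted parameters."""
        self._check_fitted()
        return forward_loglik(self.params_, self._as_series(X, lengths))

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi-decoded most likely state sequence (1-based labels)."""
        self._check_fitted()
        series = self._as_series(X, lengths)
        logb, eta = _logb_eta(self.params_, series)
        path = _kernels.viterbi_path(logb, eta, self.params_.delta, series.lengths)
        return path + 1

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Smoothed state membership probabilities (forward-backward)."""
        self._check_fitted()
        series = self._as_series(X, lengths)
        logb, eta = _logb_eta(self.params_, series)
        alpha, _ = _kernels.forward_normalised(
            logb, eta, self.params_.delta, series.lengths
        )
        beta = _kernels.backward_normalised(logb, eta, series.lengths)
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        return post

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "params": self.params_.to_dict(),
            "working_params": self.working_params_.tolist(),
            "log_likelihood": self.log_likelihood_,
            "bic": self.bic_,
            "n_parameters": self.n_parameters_,
            "n_obs": self.n_obs_,
            "covariance": None
            if self.covariance_ is None
            else self.covariance_.tolist(),
            "start_log_likelihoods": self.start_log_likelihoods_.tolist(),
            "best_start": self.best_start_,
            "converged": self.converged_,
            "feature_names": self.feature_names_in_,
            "n_states": int(self.n_states),
            "estimate_zero_mass": self.estimate_zero_mass_,
            "random_state": self.random_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovementHMM":
        m = cls(n_states=d["n_states"], random_state=d.get("random_state"))
        m.params_ = HMMParameters.from_dict(d["params"])
        m.working_params_ = np.array(d["working_params"])
        m.log_likelihood_ = d["log_likelihood"]
        m.bic_ = d["bic"]
        m.n_parameters_ = d["n_parameters"]
        m.n_obs_ = d["n_obs"]
        m.covariance_ = (
            None if d["covariance"] is None else np.array(d["covariance"])
        )
        m.start_log_likelihoods_ = np.array(d["start_log_likelihoods"])
        m.best_start_ = d["best_start"]
        m.converged_ = d["converged"]
        m.feature_names_in_ = d["feature_names"]
        m.n_features_in_ = len(d["feature_names"])
        m.estimate_zero_mass_ = d["estimate_zero_mass"]
        return m


def moment_start(series: StepAngleSeries, n_states: int) -> np.ndarray:
    """Deterministic moment-based starting vector.

    Positive steps are split into ``n_states`` quantile groups; each
    group's mean/sd seed that state's gamma parameters.  The slowest
    state starts with an angle mean of pi (GPS jitter reverses headings),
    the rest at 0; concentrations start at 1, transition intercepts
    sticky, slopes zero.  Useful as a reliable companion to random starts
    in model-selection loops.
    """
    K = int(n_states)
    pos = np.sort(series.steps[np.isfinite(series.steps) & (series.steps > 0)])
    if pos.size < 5 * K:
        raise ValueError("too few positive steps for a moment-based start")
    groups = np.array_split(pos, K)
    mu = np.array([max(g.mean(), 1e-6) for g in groups])
    sigma = np.array([max(g.std(), m / 2) for g, m in zip(groups, mu)])
    phi = np.concatenate([[np.pi], np.zeros(K - 1)])
    beta = np.zeros((series.design.shape[1], K * (K - 1)))
    beta[0] = -2.0
    params = HMMParameters(
        step_mean=mu,
        step_sd=sigma,
        angle_mean=phi,
        angle_conc=np.ones(K),
        beta=beta,
        delta=np.full(K, 1.0 / K),
    )
    return natural_to_working(params, False)


def fit_hmm(
    series: StepAngleSeries,
    n_states: int = 3,
    n_starts: int = 30,
    seed: int | None = None,
    **kwargs,
) -> MovementHMM:
    """Functional wrapper over :class:`MovementHMM`."""
    return MovementHMM(
        n_states=n_states, n_starts=n_starts, random_state=seed, **kwargs
    ).fit(series)
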