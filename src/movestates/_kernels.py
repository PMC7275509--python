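"""Numba-compiled numerical kernels for the HMM likelihood machinery.

Everything here works on plain float64 arrays.  Missing observations are
encoded as NaN and contribute an emission factor of 1 (log-factor 0), so a
fully missing time step carries no information but keeps the chain aligned
to the hourly grid.

Layout conventions (shared with :mod:`movestates.hmm`):

* ``logb``: (T, K) log state-dependent densities,
* ``eta``: (T, K*(K-1)) linear predictors of the multinomial logit, column
  order per :func:`movestates.containers.transition_pairs`; the implied
  Gamma(t) is the row-wise softmax with the self-transition pinned at
  linear predictor 0,
* bursts are stacked; ``lengths`` gives steps per burst and the recursion
  restarts from ``delta`` at every burst start.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_NINF = -1.0e300


@njit(cache=True)
def emission_logdens(
    steps,
    angles,
    shape,
    rate,
    lgamma_shape,
    zero_mass,
    angle_mean,
    angle_conc,
    log_norm_vm,
):
    """Per-step, per-state log emission densities.

    ``shape``/``rate`` parameterise the gamma step distribution;
    ``lgamma_shape`` = lgamma(shape) and ``log_norm_vm`` = log(2*pi*I0(kappa))
    are precomputed by the caller.  An exact zero step takes the zero-mass
    point probability; positive steps take (1 - zero_mass) times the gamma
    density.
    """
    T = steps.shape[0]
    K = shape.shape[0]
    logb = np.zeros((T, K))
    for t in range(T):
        s = steps[t]
        a = angles[t]
        step_ok = not math.isnan(s)
        ang_ok = not math.isnan(a)
        for i in range(K):
            v = 0.0
            if step_ok:
                if s > 0.0:
                    v += (
                        math.log(1.0 - zero_mass[i])
                        + shape[i] * math.log(rate[i])
                        - lgamma_shape[i]
                        + (shape[i] - 1.0) * math.log(s)
                        - rate[i] * s
                    )
                else:
                    v += math.log(zero_mass[i]) if zero_mass[i] > 0.0 else _NINF
            if ang_ok:
                v += angle_conc[i] * math.cos(a - angle_mean[i]) - log_norm_vm[i]
            logb[t, i] = v
    return logb


@njit(cache=True)
def _gamma_row(eta_t, K, out):
    """Fill ``out`` (K, K) with the softmax transition matrix at one step."""
    c = 0
    for i in range(K):
        denom = 1.0
        for j in range(K):
            if j == i:
                out[i, j] = 1.0
                continue
            e = math.exp(eta_t[c])
            out[i, j] = e
            denom += e
            c += 1
        for j in range(K):
            out[i, j] /= denom


@njit(cache=True)
def forward_logsum(logb, eta, delta, lengths):
    """Scaled forward recursion; returns the total log-likelihood.

    Per-burst log-likelihoods add; the recursion is rescaled at every step
    so arbitrarily long bursts stay in range.
    """
    K = logb.shape[1]
    G = np.empty((K, K))
    alpha = np.empty(K)
    nxt = np.empty(K)
    ll = 0.0
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        # initial step of the burst
        m = logb[t0, 0]
        for i in range(1, K):
            if logb[t0, i] > m:
                m = logb[t0, i]
        if m <= _NINF:
            return -np.inf
        c = 0.0
        for i in range(K):
            alpha[i] = delta[i] * math.exp(logb[t0, i] - m)
            c += alpha[i]
        if c <= 0.0 or math.isnan(c):
            return -np.inf
        ll += math.log(c) + m
        for i in range(K):
            alpha[i] /= c
        for t in range(t0 + 1, t0 + T):
            _gamma_row(eta[t - 1], K, G)
            m = logb[t, 0]
            for i in range(1, K):
                if logb[t, i] > m:
                    m = logb[t, i]
            if m <= _NINF:
                return -np.inf
            c = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[i] * G[i, j]
                nxt[j] = acc * math.exp(logb[t, j] - m)
                c += nxt[j]
            if c <= 0.0 or math.isnan(c):
                return -np.inf
            ll += math.log(c) + m
            for j in range(K):
                alpha[j] = nxt[j] / c
        t0 += T
    return ll


@njit(cache=True)
def forward_normalised(logb, eta, delta, lengths):
    """Normalised forward probabilities and one-step-ahead state weights.

    Returns ``(alpha, pred)`` where ``alpha[t]`` is P(state at t | obs up to
    t) and ``pred[t]`` is P(state at t | obs before t) within the step's
    burst (``pred`` at a burst start equals ``delta``).
    """
    T_all, K = logb.shape
    alpha = np.empty((T_all, K))
    pred = np.empty((T_all, K))
    G = np.empty((K, K))
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        for i in range(K):
            pred[t0, i] = delta[i]
        for t in range(t0, t0 + T):
            if t > t0:
                _gamma_row(eta[t - 1], K, G)
                for j in range(K):
                    acc = 0.0
                    for i in range(K):
                        acc += alpha[t - 1, i] * G[i, j]
                    pred[t, j] = acc
            m = logb[t, 0]
            for i in range(1, K):
                if logb[t, i] > m:
                    m = logb[t, i]
            c = 0.0
            for i in range(K):
                alpha[t, i] = pred[t, i] * math.exp(logb[t, i] - m)
                c += alpha[t, i]
            for i in range(K):
                alpha[t, i] /= c
        t0 += T
    return alpha, pred


@njit(cache=True)
def backward_normalised(logb, eta, lengths):
    """Scaled backward probabilities (each row normalised to sum 1)."""
    T_all, K = logb.shape
    beta = np.empty((T_all, K))
    G = np.empty((K, K))
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        for i in range(K):
            beta[t0 + T - 1, i] = 1.0 / K
        for t in range(t0 + T - 2, t0 - 1, -1):
            _gamma_row(eta[t], K, G)
            m = logb[t + 1, 0]
            for i in range(1, K):
                if logb[t + 1, i] > m:
                    m = logb[t + 1, i]
            c = 0.0
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += G[i, j] * math.exp(logb[t + 1, j] - m) * beta[t + 1, j]
                beta[t, i] = acc
                c += acc
            for i in range(K):
                beta[t, i] /= c
        t0 += T
    return beta


@njit(cache=True)
def forward_backward_grad(logb, eta, delta, lengths):
    """Log-likelihood plus the adjoint quantities needed for its gradient.

    Returns ``(ll, gamma, omega, gdelta)``:

    * ``gamma[t, i]``: smoothed posterior P(state_t = i | all obs),
    * ``omega[t, c]``: d ll / d eta[t, c] for the transition leaving step t
      (zero on the last step of each burst),
    * ``gdelta[k]``: d ll / d delta_k propagated through the softmax of the
      initial-distribution logits (summed over bursts).
    """
    T_all, K = logb.shape
    npair = eta.shape[1]
    gamma = np.zeros((T_all, K))
    omega = np.zeros((T_all, npair))
    gdelta = np.zeros(K)
    alphahat = np.empty((T_all, K))
    bscaled = np.empty((T_all, K))
    G = np.empty((K, K))
    xi = np.empty((K, K))
    bb = np.empty(K)
    betahat = np.empty(K)
    newbeta = np.empty(K)
    ll = 0.0
    # forward pass, storing filtered probabilities and scaled emissions
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        m = logb[t0, 0]
        for i in range(1, K):
            if logb[t0, i] > m:
                m = logb[t0, i]
        if m <= _NINF:
            return -np.inf, gamma, omega, gdelta
        c = 0.0
        for i in range(K):
            bscaled[t0, i] = math.exp(logb[t0, i] - m)
            alphahat[t0, i] = delta[i] * bscaled[t0, i]
            c += alphahat[t0, i]
        if c <= 0.0 or math.isnan(c):
            return -np.inf, gamma, omega, gdelta
        ll += math.log(c) + m
        for i in range(K):
            alphahat[t0, i] /= c
        for t in range(t0 + 1, t0 + T):
            _gamma_row(eta[t - 1], K, G)
            m = logb[t, 0]
            for i in range(1, K):
                if logb[t, i] > m:
                    m = logb[t, i]
            if m <= _NINF:
                return -np.inf, gamma, omega, gdelta
            c = 0.0
            for j in range(K):
                bscaled[t, j] = math.exp(logb[t, j] - m)
                acc = 0.0
                for i in range(K):
                    acc += alphahat[t - 1, i] * G[i, j]
                alphahat[t, j] = acc * bscaled[t, j]
                c += alphahat[t, j]
            if c <= 0.0 or math.isnan(c):
                return -np.inf, gamma, omega, gdelta
            ll += math.log(c) + m
            for j in range(K):
                alphahat[t, j] /= c
        t0 += T
    # backward pass: smoothed posteriors and transition adjoints
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        last = t0 + T - 1
        s = 0.0
        for i in range(K):
            betahat[i] = 1.0
            gamma[last, i] = alphahat[last, i]
            s += gamma[last, i]
        for i in range(K):
            gamma[last, i] /= s
        for t in range(last - 1, t0 - 1, -1):
            _gamma_row(eta[t], K, G)
            for j in range(K):
                bb[j] = bscaled[t + 1, j] * betahat[j]
            s = 0.0
            for i in range(K):
                for j in range(K):
                    xi[i, j] = alphahat[t, i] * G[i, j] * bb[j]
                    s += xi[i, j]
            if s <= 0.0 or math.isnan(s):
                return -np.inf, gamma, omega, gdelta
            for i in range(K):
                g = 0.0
                for j in range(K):
                    xi[i, j] /= s
                    g += xi[i, j]
                gamma[t, i] = g
            c = 0
            for i in range(K):
                for j in range(K):
                    if j != i:
                        omega[t, c] = xi[i, j] - gamma[t, i] * G[i, j]
                        c += 1
            sb = 0.0
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += G[i, j] * bb[j]
                newbeta[i] = acc
                sb += acc
            if sb <= 0.0 or math.isnan(sb):
                return -np.inf, gamma, omega, gdelta
            for i in range(K):
                betahat[i] = newbeta[i] / sb
        for k in range(K):
            gdelta[k] += gamma[t0, k] - delta[k]
        t0 += T
    return ll, gamma, omega, gdelta


@njit(cache=True)
def viterbi_path(logb, eta, delta, lengths):
    """Most likely state path per burst (log-space DP), 0-based labels.

    Ties are broken toward the lower state index.
    """
    T_all, K = logb.shape
    path = np.empty(T_all, np.int64)
    G = np.empty((K, K))
    score = np.empty((T_all, K))
    back = np.empty((T_all, K), np.int64)
    t0 = 0
    for b in range(lengths.shape[0]):
        T = lengths[b]
        for i in range(K):
            d = delta[i]
            score[t0, i] = (math.log(d) if d > 0.0 else _NINF) + logb[t0, i]
            back[t0, i] = 0
        for t in range(t0 + 1, t0 + T):
            _gamma_row(eta[t - 1], K, G)
            for j in range(K):
                best = _NINF * 2.0
                arg = 0
                for i in range(K):
                    g = G[i, j]
                    v = score[t - 1, i] + (math.log(g) if g > 0.0 else _NINF)
                    if v > best:  # strict: ties keep the lower index
                        best = v
                        arg = i
                score[t, j] = best + logb[t, j]
                back[t, j] = arg
        last = t0 + T - 1
        best = score[last, 0]
        arg = 0
        for i in range(1, K):
            if score[last, i] > best:
                best = score[last, i]
                arg = i
        path[last] = arg
        for t in range(last, t0, -1):
            arg = back[t, arg]
            path[t - 1] = arg
        t0 += T
    return path


def build_transition_matrices(beta: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Dense (T, K, K) stack of transition matrices Gamma(t).

    Vectorised numpy version used by the public API and the stationary
    analyses; the fitting loop uses the on-the-fly kernel instead.
    """
    beta = np.atleast_2d(np.asarray(beta, float))
    design = np.atleast_2d(np.asarray(design, float))
    if design.shape[1] != beta.shape[0]:
        raise ValueError(
            f"design has {design.shape[1]} columns but beta has {beta.shape[0]} rows"
        )
    n_pairs = beta.shape[1]
    K = int(round((1 + math.sqrt(1 + 4 * n_pairs)) / 2))
    if K * (K - 1) != n_pairs:
        raise ValueError(f"beta column count {n_pairs} is not K*(K-1) for integer K")
    eta_flat = design @ beta  # (T, K(K-1))
    T = design.shape[0]
    eta = np.zeros((T, K, K))
    c = 0
    for i in range(K):
        for j in range(K):
            if j != i:
                eta[:, i, j] = eta_flat[:, c]
                c += 1
    eta -= eta.max(axis=2, keepdims=True)
    G = np.exp(eta)
    G /= G.sum(axis=2, keepdims=True)
    return G
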