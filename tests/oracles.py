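"""Independent brute-force oracles used to validate the HMM machinery.

Deliberately naive implementations (exhaustive path enumeration, explicit
softmax, power iteration) kept free of any package internals beyond the
parameter container, so they can disagree with the fast implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import special, stats

from movestates.containers import HMMParameters, transition_pairs


def oracle_emission(params: HMMParameters, step, angle, state: int) -> float:
    """Emission probability of one observation in one state (factor 1 for
    missing components)."""
    p = 1.0
    if step is not None and np.isfinite(step):
        mu = params.step_mean[state]
        sd = params.step_sd[state]
        zeta = params.zero_mass[state]
        if step == 0:
            p *= zeta
        else:
            a = mu**2 / sd**2
            p *= (1 - zeta) * stats.gamma.pdf(step, a=a, scale=sd**2 / mu)
    if angle is not None and np.isfinite(angle):
        kap = params.angle_conc[state]
        p *= np.exp(kap * np.cos(angle - params.angle_mean[state])) / (
            2 * np.pi * special.i0(kap)
        )
    return p


def oracle_transition_matrix(params: HMMParameters, z: np.ndarray) -> np.ndarray:
    """Explicit softmax transition matrix for one design row."""
    K = params.n_states
    eta = np.zeros((K, K))
    for c, (i, j) in enumerate(transition_pairs(K)):
        eta[i, j] = float(z @ params.beta[:, c])
    G = np.exp(eta)
    return G / G.sum(axis=1, keepdims=True)


def oracle_path_prob(params, steps, angles, design, path) -> float:
    prob = params.delta[path[0]] * oracle_emission(params, steps[0], angles[0], path[0])
    for t in range(1, len(path)):
        G = oracle_transition_matrix(params, design[t - 1])
        prob *= G[path[t - 1], path[t]] * oracle_emission(
            params, steps[t], angles[t], path[t]
        )
    return prob


def _tables(params, steps, angles, design):
    """Precomputed emission and transition tables for fast enumeration."""
    K = params.n_states
    T = len(steps)
    B = np.array(
        [[oracle_emission(params, steps[t], angles[t], i) for i in range(K)]
         for t in range(T)]
    )
    G = np.array([oracle_transition_matrix(params, design[t]) for t in range(T)])
    return B, G


def oracle_loglik(params, steps, angles, design) -> float:
    """Log-likelihood by exhaustive enumeration over all K^T state paths."""
    K = params.n_states
    T = len(steps)
    B, G = _tables(params, steps, angles, design)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = params.delta[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= G[t - 1, path[t - 1], path[t]] * B[t, path[t]]
        total += p
    return float(np.log(total))


def oracle_viterbi(params, steps, angles, design) -> np.ndarray:
    """Most likely path by exhaustive argmax (first maximum wins, which in
    lexicographic product order prefers lower state indices)."""
    K = params.n_states
    T = len(steps)
    B, G = _tables(params, steps, angles, design)
    best, best_p = None, -1.0
    for path in itertools.product(range(K), repeat=T):
        p = params.delta[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= G[t - 1, path[t - 1], path[t]] * B[t, path[t]]
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


def oracle_stationary(G: np.ndarray, n_iter: int = 10_000) -> np.ndarray:
    """Stationary distribution by power iteration."""
    d = np.full(G.shape[0], 1.0 / G.shape[0])
    for _ in range(n_iter):
        nd = d @ G
        if np.max(np.abs(nd - d)) < 1e-15:
            return nd
        d = nd
    return d


def random_parameters(rng, K: int, p: int = 1, zero_mass: bool = False):
    """Random valid parameter set for property tests."""
    mu = np.sort(rng.uniform(5.0, 400.0, K))
    params = HMMParameters(
        step_mean=mu,
        step_sd=mu * rng.uniform(0.3, 1.5, K),
        zero_mass=rng.uniform(0.05, 0.3, K) if zero_mass else None,
        angle_mean=rng.uniform(-np.pi + 1e-6, np.pi, K),
        angle_conc=rng.uniform(0.05, 8.0, K),
        beta=rng.normal(0.0, 1.0, (p, K * (K - 1))),
        delta=rng.dirichlet(np.ones(K)),
    )
    return params


def random_observations(rng, T: int, p: int = 1, with_missing: bool = False):
    steps = rng.gamma(2.0, 60.0, T)
    angles = rng.uniform(-np.pi, np.pi, T)
    angles[0] = np.nan
    if with_missing and T > 2:
        steps[rng.integers(1, T)] = np.nan
        angles[rng.integers(1, T)] = np.nan
    design = np.column_stack([np.ones(T), rng.normal(0.0, 1.0, (T, p - 1))])
    return steps, angles, design
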