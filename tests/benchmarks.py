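"""Simulation studies validating the pipeline end to end.

Shared between the acceptance test suite and ``scripts/acceptance.py``;
every routine generates its own data from a seed, runs the package, and
returns summary quantities.  Problem sizes are chosen so the full set
runs on one CPU in well under half an hour (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from movestates.design import DesignEncoder, candidate_blocks
from movestates.hmm import HMMFitError, MovementHMM, forward_loglik
from movestates.inference import mc_confidence_bands, stationary_distribution
from movestates.preprocessing import bursts_to_series, split_bursts
from movestates.simulate import (
    AR1Spec,
    SimulationScenario,
    default_parameters,
    default_scenario,
    simulate_covariates,
    simulate_track,
    simulate_tracks,
    tracks_to_series,
)

from .conftest import make_series
from .oracles import (
    oracle_loglik,
    oracle_stationary,
    oracle_viterbi,
    random_observations,
    random_parameters,
)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# -- study: likelihood and Viterbi against exhaustive enumeration -------

def enumeration_check(n_cases: int = 200, seed: int = 0) -> dict:
    """Forward log-likelihood and Viterbi paths vs brute-force enumeration
    over all K^T paths, for random parameterisations with K in {2,3} and
    T in 2..8 (with occasional missing observations)."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    mismatches = 0
    for c in range(n_cases):
        K = int(rng.integers(2, 4))
        T = int(rng.integers(2, 9))
        p = int(rng.integers(1, 4))
        params = random_parameters(rng, K, p, zero_mass=c % 5 == 4)
        steps, angles, design = random_observations(
            rng, T, p, with_missing=c % 3 == 2
        )
        if c % 5 == 4:
            steps[int(rng.integers(T))] = 0.0
        series = make_series(steps, angles, design)
        ll = forward_loglik(params, series)
        max_diff = max(max_diff, abs(ll - oracle_loglik(params, steps, angles, design)))
        model = MovementHMM(n_states=K)
        model.params_ = params
        model.estimate_zero_mass_ = True
        path = model.predict(series) - 1
        if not np.array_equal(path, oracle_viterbi(params, steps, angles, design)):
            mismatches += 1
    return {
        "n_cases": n_cases,
        "loglik_max_abs_diff": max_diff,
        "viterbi_agreement": 1.0 - mismatches / n_cases,
    }


# -- study: stationary distribution solve -------------------------------

def stationary_check(n_matrices: int = 1000, seed: int = 0) -> dict:
    """delta Gamma = delta residuals and power-iteration agreement on
    random ergodic 3-state matrices."""
    rng = np.random.default_rng(seed)
    max_resid = 0.0
    max_power_diff = 0.0
    for _ in range(n_matrices):
        G = rng.dirichlet(np.ones(3) * rng.uniform(0.3, 5.0), size=3)
        d = stationary_distribution(G)
        max_resid = max(max_resid, float(np.max(np.abs(d @ G - d))))
        max_power_diff = max(
            max_power_diff, float(np.max(np.abs(d - oracle_stationary(G))))
        )
    return {
        "n_matrices": n_matrices,
        "max_residual": max_resid,
        "max_power_iteration_diff": max_power_diff,
    }


# -- study: full-pipeline parameter recovery ----------------------------

def recovery_study(
    seed: int = 0,
    n_animals: int = 5,
    n_hours: int = 5001,
    n_starts: int = 30,
) -> dict:
    """Simulate the canonical 3-state scenario (~25k steps across 5
    bursts), refit from scratch through the preprocessing chain, and
    compare estimates against the generative truth."""
    scenario = default_scenario(
        n_animals=n_animals, n_hours=n_hours, seed=int(_seeds(seed, 1)[0])
    )
    sims = simulate_tracks(scenario)
    bursts = []
    for s in sims:
        bursts += split_bursts(s.track)
    series = bursts_to_series(bursts, scenario.encoder())
    model = MovementHMM(
        n_states=3, n_starts=n_starts, random_state=int(_seeds(seed, 2)[1])
    ).fit(series)

    true = scenario.true_params
    est = model.params_
    rel = lambda a, b: np.abs(a - b) / np.abs(b)
    emission_rel = np.concatenate(
        [
            rel(est.step_mean, true.step_mean),
            rel(est.step_sd, true.step_sd),
            rel(est.angle_conc, true.angle_conc),
        ]
    )
    # angle means compared on the circle (absolute, since two of them are 0)
    phi_err = np.abs(
        np.angle(np.exp(1j * (est.angle_mean - true.angle_mean)))
    )
    n_beta = true.beta.size
    cov_beta = np.asarray(model.covariance_)[-n_beta:, -n_beta:]
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None)).reshape(true.beta.shape)
    beta_z = (est.beta - true.beta) / se
    # joint 3-sigma check: Mahalanobis distance of the coefficient vector
    # under the estimator covariance, rescaled so that the two-sided
    # 3-sigma chi-square quantile maps to 3 (a max over 24 marginal
    # z-scores would reject ~6% of correct fits by chance alone)
    from scipy.stats import chi2

    diff = (est.beta - true.beta).ravel()
    d2 = float(diff @ np.linalg.pinv(cov_beta) @ diff)
    z_joint = 3.0 * np.sqrt(d2 / chi2.ppf(1.0 - 0.0027, n_beta))

    truth_states = np.concatenate([s.true_states for s in sims])
    accuracy = float(np.mean(model.predict(series) == truth_states))
    return {
        "n_steps": series.n_steps,
        "n_bursts": series.n_bursts,
        "model": model,
        "scenario": scenario,
        "series": series,
        "emission_max_rel_error": float(emission_rel.max()),
        "angle_mean_max_abs_error": float(phi_err.max()),
        "beta_joint_z": float(z_joint),
        "beta_max_abs_z": float(np.max(np.abs(beta_z))),
        "decoding_accuracy": accuracy,
    }


# -- study: forward selection sanity ------------------------------------

_FULL_SPEC = {
    "snow_depth": {"kind": "continuous"},
    "hour": {"kind": "cyclic", "period": 24},
    "temperature": {"kind": "continuous"},
    "wind_speed": {"kind": "continuous"},
    "landcover": {"kind": "categorical", "reference": "bare_ground"},
}


def _selection_scenario(seed: int, n_hours: int) -> SimulationScenario:
    snow = AR1Spec(mean=0.35, sd=0.12, rho=0.98)
    true = default_parameters(n_design=2)
    true.beta[1] = [-0.5, -0.3, 0.8, -0.3, 0.8, 0.0]
    return SimulationScenario(
        true_params=true,
        design_spec={
            "snow_depth": {
                "kind": "continuous", "center": snow.mean, "scale": snow.sd
            }
        },
        n_animals=1,
        n_hours=n_hours,
        snow_depth=snow,
        seed=seed,
    )


def selection_study(
    n_reps: int = 20, seed: int = 0, n_hours: int = 2501, n_starts: int = 4
) -> dict:
    """Replicated forward selection with snow depth the only active
    covariate among five candidate blocks; success means the active block
    is adopted first and selection then stops."""
    from movestates.selection import ForwardBICSelector

    seeds = _seeds(seed, 2 * n_reps)
    successes = 0
    first_picks = []
    for r in range(n_reps):
        scenario = _selection_scenario(int(seeds[2 * r]), n_hours)
        sims = simulate_tracks(scenario)
        enc = DesignEncoder(_FULL_SPEC)
        series = bursts_to_series(split_bursts(sims[0].track), enc)
        sel = ForwardBICSelector(
            candidate_blocks(enc),
            n_starts=n_starts,
            final_n_starts=n_starts,
            random_state=int(seeds[2 * r + 1]),
        ).fit(series)
        first_picks.append(sel.selected_blocks_[:1])
        if sel.selected_blocks_ == ["snow_depth"]:
            successes += 1
    return {
        "n_reps": n_reps,
        "success_rate": successes / n_reps,
        "first_picks": first_picks,
    }


# -- study: Monte Carlo confidence-band coverage ------------------------

def coverage_study(
    n_reps: int = 100,
    seed: int = 0,
    n_hours: int = 801,
    n_starts: int = 8,
    n_draws: int = 300,
    n_grid: int = 8,
) -> dict:
    """Pointwise 95% bands on the snow-depth stationary curve: fraction of
    grid points (per replicate, averaged over replicates) whose band
    covers the curve implied by the generative parameters.

    Uses the snow-only transition design (the smallest model with a
    non-trivial curve) so each ~800-step replicate carries adequate
    information per coefficient.  Replicates whose fit does not reach an
    interior optimum (non-positive-definite observed information, the
    band method's precondition) count as fit failures, not as coverage
    misses; with 8 starts these are rare.
    """
    proto = _selection_scenario(0, n_hours)
    snow = proto.snow_depth
    grid = np.linspace(snow.mean - 1.5 * snow.sd, snow.mean + 1.5 * snow.sd, n_grid)

    seeds = _seeds(seed, 3 * n_reps)
    per_rep = []
    failures = 0
    true_curve = None
    for r in range(n_reps):
        scenario = _selection_scenario(int(seeds[3 * r]), n_hours)
        sim = simulate_track(scenario)
        series, _ = tracks_to_series([sim], scenario)
        enc = scenario.encoder().fit(simulate_covariates(scenario))
        if true_curve is None:
            truth_model = MovementHMM(n_states=3)
            truth_model.params_ = scenario.true_params
            truth_model.estimate_zero_mass_ = False
            from movestates.inference import stationary_curve

            true_curve = stationary_curve(
                truth_model, enc, "snow_depth", grid
            ).probs
        try:
            model = MovementHMM(
                n_states=3, n_starts=n_starts, random_state=int(seeds[3 * r + 1])
            ).fit(series)
            info = 0.5 * (model.covariance_ + model.covariance_.T)
            if not np.all(np.linalg.eigvalsh(info) > 0):
                failures += 1
                continue
            curve = mc_confidence_bands(
                model, enc, "snow_depth", grid,
                n_draws=n_draws, seed=int(seeds[3 * r + 2]),
            )
        except (HMMFitError, ValueError):
            failures += 1
            continue
        covered = (curve.lower - 1e-12 <= true_curve) & (
            true_curve <= curve.upper + 1e-12
        )
        per_rep.append(float(covered.mean()))
    per_rep = np.asarray(per_rep)
    return {
        "n_reps": len(per_rep),
        "n_failures": failures,
        "coverage": float(per_rep.mean()),
        "coverage_se": float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))),
    }


# -- study: preprocessing boundary rules --------------------------------

def preprocessing_boundary_checks() -> dict:
    """The six boundary fixtures: gap retention/splitting at 10 vs 11 h,
    burst filtering at 671 vs 672 h, season labelling at 47 vs 48 h
    snow-free runs."""
    import pandas as pd

    from movestates.preprocessing import assign_seasons, filter_bursts

    def track(n, gap=None):
        ts = pd.date_range("2014-01-01", periods=n, freq="h")
        df = pd.DataFrame(
            {"animal_id": "a", "timestamp": ts,
             "x": 10.0 * np.arange(n), "y": 0.0}
        )
        if gap:
            s, l = gap
            df = df.drop(df.index[s : s + l]).reset_index(drop=True)
        return df

    results = {}
    b = split_bursts(track(48, gap=(10, 10)))
    results["gap_10h_one_burst"] = len(b) == 1 and int(b[0]["x"].isna().sum()) == 10
    results["gap_11h_two_bursts"] = len(split_bursts(track(48, gap=(10, 11)))) == 2
    kept, _ = filter_bursts([track(671)])
    results["burst_671h_removed"] = len(kept) == 0
    kept, _ = filter_bursts([track(672)])
    results["burst_672h_retained"] = len(kept) == 1

    def seasons(free_hours):
        t = track(200)
        snow = np.full(200, 0.5)
        snow[50 : 50 + free_hours] = 0.0
        t["snow_depth"] = snow
        return [p.attrs["season"] for p in assign_seasons(t)]

    results["snowfree_47h_all_winter"] = seasons(47) == ["winter"]
    results["snowfree_48h_has_summer"] = seasons(48) == ["winter", "summer", "winter"]
    return {
        "n_checks": len(results),
        "n_passed": sum(results.values()),
        "detail": results,
    }
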