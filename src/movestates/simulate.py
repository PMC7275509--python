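"""Synthetic covariates and movement tracks from known HMM parameters.

The generator emulates the structure of hourly arctic-ungulate telemetry:
regular hourly sampling with occasional multi-hour fix gaps, three latent
behavioural states with distinct step/turning-angle distributions, and
transition probabilities modulated by a diel cycle and by slowly varying
environmental covariates (snow depth, temperature, wind), plus a
categorical landcover series and a solar light schedule at high latitude.

Everything is driven by a :class:`SimulationScenario`; the same seed
yields bitwise-identical output.  Positions live in an abstract planar
metre coordinate system - the model consumes only steps and angles, so no
geodesy is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HMMParameters, StepAngleSeries
from .design import DesignEncoder
from ._kernels import build_transition_matrices
from .solar import compute_light

__all__ = [
    "SinusoidSpec",
    "AR1Spec",
    "MarkovCategorySpec",
    "GapSpec",
    "SimulationScenario",
    "SimulatedTrack",
    "default_parameters",
    "default_scenario",
    "simulate_covariates",
    "simulate_track",
    "simulate_tracks",
    "degrade_track",
    "tracks_to_series",
]


@dataclass
class SinusoidSpec:
    """Exactly 24 h-periodic diel covariate: mean + amplitude * sin."""

    mean: float
    amplitude: float
    phase_hour: float = 0.0


@dataclass
class AR1Spec:
    """Stationary AR(1): x_t = mean + rho (x_{t-1} - mean) + innovation.

    ``sd`` is the stationary (marginal) standard deviation; innovations
    have variance sd^2 (1 - rho^2).
    """

    mean: float
    sd: float
    rho: float

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("AR(1) autocorrelation must lie in (-1, 1)")
        if self.sd < 0:
            raise ValueError("AR(1) sd must be non-negative")


@dataclass
class MarkovCategorySpec:
    """Sticky categorical chain: stay with ``stay_prob``, else uniform."""

    levels: tuple[str, ...] = ("bare_ground", "sparse_vegetation", "dense_vegetation")
    stay_prob: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ValueError("stay_prob must lie in [0, 1]")


@dataclass
class GapSpec:
    """Missing-fix runs: per-hour start probability, geometric lengths."""

    start_prob: float = 0.0
    mean_length: float = 3.0
    forced_gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.start_prob <= 1.0:
            raise ValueError("gap start probability must lie in [0, 1]")
        if self.mean_length < 1.0:
            raise ValueError("mean gap length must be >= 1 hour")


@dataclass
class SimulationScenario:
    """Full description of one simulated study condition."""

    true_params: HMMParameters
    design_spec: dict
    n_animals: int = 5
    start_time: str = "2014-01-01 00:00"
    n_hours: int = 5001
    season: str = "winter"
    latitude: float = 74.5
    longitude: float = -21.0
    temperature: SinusoidSpec = field(
        default_factory=lambda: SinusoidSpec(mean=-15.0, amplitude=4.0, phase_hour=14.0)
    )
    snow_depth: AR1Spec = field(
        default_factory=lambda: AR1Spec(mean=0.35, sd=0.12, rho=0.98)
    )
    wind_speed: AR1Spec = field(
        default_factory=lambda: AR1Spec(mean=5.0, sd=2.0, rho=0.9)
    )
    landcover: MarkovCategorySpec = field(default_factory=MarkovCategorySpec)
    gap_spec: GapSpec = field(default_factory=GapSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.season not in ("summer", "winter"):
            raise ValueError("season must be 'summer' or 'winter'")

    def encoder(self) -> DesignEncoder:
        return DesignEncoder(self.design_spec)


@dataclass
class SimulatedTrack:
    """One animal's simulated track plus the generative truth.

    ``track`` holds the hourly fixes (rows with NaN positions are missing
    fixes); ``true_states`` are 1-based per-step state labels, and
    ``steps``/``angles`` the exact emission draws (NaN angle where the
    turning angle is undefined).
    """

    track: pd.DataFrame
    true_states: np.ndarray
    steps: np.ndarray
    angles: np.ndarray
    design: np.ndarray


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _ar1(spec: AR1Spec, n: int, rng) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(spec.mean, spec.sd)
    innov_sd = spec.sd * np.sqrt(1.0 - spec.rho**2)
    eps = rng.normal(0.0, innov_sd, n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = spec.mean + spec.rho * (x[t - 1] - spec.mean) + eps[t - 1]
    return x


def simulate_covariates(
    scenario: SimulationScenario, animal: int = 0
) -> pd.DataFrame:
    """Hourly covariate table for one animal.

    Temperature is an exactly 24 h-periodic sinusoid; snow depth and wind
    speed follow stationary AR(1) processes; landcover is a sticky
    categorical Markov chain; light comes from the solar schedule at the
    scenario's latitude/longitude.
    """
    rng = np.random.default_rng([scenario.seed, 1, animal])
    n = scenario.n_hours
    timestamps = pd.date_range(scenario.start_time, periods=n, freq="h")
    hour = timestamps.hour.to_numpy(float)
    tspec = scenario.temperature
    temperature = tspec.mean + tspec.amplitude * np.sin(
        2.0 * np.pi * (hour - tspec.phase_hour) / 24.0
    )
    snow = _ar1(scenario.snow_depth, n, rng)
    wind = _ar1(scenario.wind_speed, n, rng)
    levels = list(scenario.landcover.levels)
    L = len(levels)
    lc_idx = np.empty(n, int)
    lc_idx[0] = rng.integers(L)
    stay = scenario.landcover.stay_prob
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    jumps = rng.integers(1, L, size=max(n - 1, 0))
    for t in range(1, n):
        if u[t - 1] < stay:
            lc_idx[t] = lc_idx[t - 1]
        else:
            lc_idx[t] = (lc_idx[t - 1] + jumps[t - 1]) % L
    light = compute_light(scenario.latitude, scenario.longitude, timestamps)
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "hour": hour,
            "temperature": temperature,
            "snow_depth": snow,
            "wind_speed": wind,
            "landcover": [levels[i] for i in lc_idx],
            "light": light,
        }
    )


def simulate_track(scenario: SimulationScenario, animal: int = 0) -> SimulatedTrack:
    """Simulate one animal's positions from the generative HMM.

    Latent states follow the covariate-driven Markov chain; step lengths
    and turning angles are drawn from the state's gamma / von Mises
    distributions; positions are integrated from a uniform random initial
    heading.  Fix gaps are then inserted per the scenario's ``gap_spec``.
    """
    params = scenario.true_params
    K = params.n_states
    cov = simulate_covariates(scenario, animal)
    enc = scenario.encoder().fit(cov)
    design_full = enc.transform(cov)  # one row per grid hour
    if design_full.shape[1] != params.n_design:
        raise ValueError(
            f"design has {design_full.shape[1]} columns but true beta expects "
            f"{params.n_design}"
        )
    n_steps = scenario.n_hours - 1
    design = design_full[:n_steps]
    G = build_transition_matrices(params.beta, design)

    rng = np.random.default_rng([scenario.seed, 2, animal])
    states = np.empty(n_steps, int)
    u = rng.random(n_steps)
    states[0] = np.searchsorted(np.cumsum(params.delta), u[0])
    for t in range(1, n_steps):
        states[t] = np.searchsorted(np.cumsum(G[t - 1, states[t - 1]]), u[t])

    shape = params.step_mean**2 / params.step_sd**2
    scale = params.step_sd**2 / params.step_mean
    steps = rng.gamma(shape[states], scale[states])
    if np.any(params.zero_mass > 0):
        steps[rng.random(n_steps) < params.zero_mass[states]] = 0.0
    angles = rng.vonmises(params.angle_mean[states], params.angle_conc[states])
    angles[0] = np.nan  # no previous heading
    zero_prev = np.flatnonzero(steps == 0.0)
    angles[zero_prev[zero_prev < n_steps]] = np.nan  # turn into a zero step
    nxt = zero_prev + 1
    angles[nxt[nxt < n_steps]] = np.nan  # turn out of a zero step

    heading = np.empty(n_steps)
    heading[0] = rng.uniform(-np.pi, np.pi)
    for t in range(1, n_steps):
        turn = angles[t]
        heading[t] = heading[t - 1] + (0.0 if np.isnan(turn) else turn)
    x = np.concatenate([[0.0], np.cumsum(steps * np.cos(heading))])
    y = np.concatenate([[0.0], np.cumsum(steps * np.sin(heading))])

    track = cov.copy()
    track.insert(0, "animal_id", f"sim{animal:02d}")
    track.insert(2, "x", x)
    track.insert(3, "y", y)
    track = degrade_track(track, scenario.gap_spec, seed=[scenario.seed, 3, animal])
    return SimulatedTrack(
        track=track,
        true_states=states + 1,
        steps=steps,
        angles=angles,
        design=design,
    )


def simulate_tracks(scenario: SimulationScenario) -> list[SimulatedTrack]:
    return [simulate_track(scenario, a) for a in range(scenario.n_animals)]


def degrade_track(track: pd.DataFrame, gap_spec: GapSpec, seed) -> pd.DataFrame:
    """Blank out position runs to emulate missed GPS fixes.

    Timestamps stay on the hourly grid; only x/y become NaN.  Gap starts
    are Bernoulli per hour, lengths 1 + geometric with the configured
    mean; ``forced_gaps`` (start index, length) are applied afterwards.
    """
    out = track.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    if gap_spec.start_prob > 0:
        t = 0
        while t < n:
            if rng.random() < gap_spec.start_prob:
                length = 1 + (
                    rng.geometric(1.0 / gap_spec.mean_length)
                    if gap_spec.mean_length > 1
                    else 0
                )
                out.iloc[t : t + length, out.columns.get_loc("x")] = np.nan
                out.iloc[t : t + length, out.columns.get_loc("y")] = np.nan
                t += length
            t += 1
    for start, length in gap_spec.forced_gaps:
        out.iloc[start : start + length, out.columns.get_loc("x")] = np.nan
        out.iloc[start : start + length, out.columns.get_loc("y")] = np.nan
    return out


def tracks_to_series(
    sims: list[SimulatedTrack], scenario: SimulationScenario
) -> tuple[StepAngleSeries, np.ndarray]:
    """Stack simulated tracks into a model-ready series plus true states.

    Uses the generator's own drawn steps/angles and design rows (i.e. no
    preprocessing round trip), one burst per animal.
    """
    enc = scenario.encoder()
    names = None
    steps, angles, designs, truth = [], [], [], []
    for s in sims:
        steps.append(s.steps)
        angles.append(s.angles)
        designs.append(s.design)
        truth.append(s.true_states)
        if names is None:
            cov = s.track
            enc.fit(cov)
            names = list(enc.feature_names_out_)
    series = StepAngleSeries.from_bursts(steps, angles, designs, feature_names=names)
    return series, np.concatenate(truth)


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------

def default_parameters(n_design: int = 4) -> HMMParameters:
    """Three-state generative truth used across tests and examples.

    Emission scales are hourly-displacement metres typical of a large
    grazing ungulate: short undirected resting steps (GPS jitter biased
    toward 180 degree turns), tortuous foraging steps of one to a few
    hundred metres, and long directed relocation steps.  Transition
    coefficients (columns ordered resting->foraging, resting->relocating,
    foraging->resting, foraging->relocating, relocating->resting,
    relocating->foraging) encode sticky states, a diel cycle on the
    rest/forage switches, and deeper snow pushing the animal toward
    resting.
    """
    beta = np.zeros((n_design, 6))
    beta[0] = -2.0  # sticky intercepts
    if n_design >= 3:  # hour_sin, hour_cos
        beta[1] = [0.4, 0.0, -0.4, 0.0, 0.0, 0.0]
        beta[2] = [0.3, 0.0, -0.3, 0.0, 0.0, 0.2]
    if n_design >= 4:  # standardised snow depth
        beta[3] = [-0.5, -0.3, 0.8, -0.3, 0.8, 0.0]
    return HMMParameters(
        step_mean=np.array([20.0, 180.0, 600.0]),
        step_sd=np.array([15.0, 110.0, 350.0]),
        angle_mean=np.array([np.pi, 0.0, 0.0]),
        angle_conc=np.array([1.0, 0.7, 4.0]),
        beta=beta,
        delta=np.array([0.4, 0.4, 0.2]),
    )


def default_scenario(
    season: str = "winter",
    n_animals: int = 5,
    n_hours: int = 5001,
    seed: int = 0,
    gap_spec: GapSpec | None = None,
) -> SimulationScenario:
    """Canonical 3-state, 2-covariate scenario (diel cycle + AR(1) snow).

    The transition design is intercept + sin/cos of hour of day + snow
    depth standardised by its *process* mean/sd, so the generative
    coefficients are exactly comparable to estimates from a refit.
    """
    snow = AR1Spec(mean=0.35, sd=0.12, rho=0.98)
    design_spec = {
        "hour": {"kind": "cyclic", "period": 24},
        "snow_depth": {"kind": "continuous", "center": snow.mean, "scale": snow.sd},
    }
    start = "2014-01-01 00:00" if season == "winter" else "2014-07-01 00:00"
    return SimulationScenario(
        true_params=default_parameters(n_design=4),
        design_spec=design_spec,
        n_animals=n_animals,
        start_time=start,
        n_hours=n_hours,
        season=season,
        snow_depth=snow,
        gap_spec=gap_spec or GapSpec(),
        seed=seed,
    )
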