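import numpy as np
import pytest

from movestates.containers import StepAngleSeries
from movestates.simulate import default_scenario, simulate_tracks, tracks_to_series


@pytest.fixture(scope="session")
def small_scenario():
    """One animal, ~2000 steps: big enough to identify all three states."""
    return default_scenario(n_animals=1, n_hours=2001, seed=1234)


@pytest.fixture(scope="session")
def small_series(small_scenario):
    sims = simulate_tracks(small_scenario)
    series, truth = tracks_to_series(sims, small_scenario)
    return series, truth


@pytest.fixture(scope="session")
def fitted_small(small_scenario, small_series):
    """A converged fit on the small scenario, shared across read-only tests."""
    from movestates.hmm import MovementHMM

    series, _ = small_series
    model = MovementHMM(
        n_states=3, n_starts=4, random_state=7, compute_hessian=True
    ).fit(series)
    return model


def make_series(steps, angles, design):
    return StepAngleSeries(
        steps=np.asarray(steps, float),
        angles=np.asarray(angles, float),
        design=np.atleast_2d(np.asarray(design, float)),
        lengths=np.array([len(steps)]),
    )
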