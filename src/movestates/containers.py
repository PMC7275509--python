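"""Core data containers shared across the pipeline.

The pipeline moves data through three representations:

* a *track*: one animal's hourly GPS fixes as a :class:`pandas.DataFrame`
  (columns ``animal_id, timestamp, x, y`` plus covariates),
* *bursts*: gap-free hourly segments of a track (positions may be missing
  for short internal gaps), carried as DataFrames with metadata in
  ``DataFrame.attrs``,
* a :class:`StepAngleSeries`: the model-ready stack of step lengths,
  turning angles and transition design rows across one or more bursts.

Model parameters live in :class:`HMMParameters`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HMMParameters",
    "StepAngleSeries",
    "transition_pairs",
]


def transition_pairs(n_states: int) -> list[tuple[int, int]]:
    """Ordered off-diagonal state pairs (i, j), i != j, 0-based, row-major.

    This fixes the column order of the transition coefficient matrix: one
    column per pair, rows of the source state grouped together.
    """
    return [(i, j) for i in range(n_states) for j in range(n_states) if j != i]


@dataclass
class HMMParameters:
    """Natural-scale parameters of the bivariate movement HMM.

    Emissions are gamma (step length, mean/sd parameterisation, optional
    point mass at zero) and von Mises (turning angle).  Transition
    probabilities follow a multinomial logit in the design covariates with
    the self-transition as reference category.

    Parameters
    ----------
    step_mean, step_sd : (K,) arrays, metres, > 0
    zero_mass : (K,) array in [0, 1); probability of an exact zero step
    angle_mean : (K,) array, radians in (-pi, pi]
    angle_conc : (K,) array, von Mises concentration, > 0
    beta : (p, K*(K-1)) array of transition coefficients; row 0 is the
        intercept, columns ordered as :func:`transition_pairs`
    delta : (K,) initial state distribution (shared across bursts)
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    angle_mean: np.ndarray
    angle_conc: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    zero_mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.step_mean = np.asarray(self.step_mean, float)
        self.step_sd = np.asarray(self.step_sd, float)
        self.angle_mean = np.asarray(self.angle_mean, float)
        self.angle_conc = np.asarray(self.angle_conc, float)
        self.beta = np.atleast_2d(np.asarray(self.beta, float))
        self.delta = np.asarray(self.delta, float)
        if self.zero_mass is None:
            self.zero_mass = np.zeros_like(self.step_mean)
        else:
            self.zero_mass = np.asarray(self.zero_mass, float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.step_mean.size

    @property
    def n_design(self) -> int:
        return self.beta.shape[0]

    def validate(self) -> None:
        K = self.n_states
        if K < 2:
            raise ValueError(f"need at least 2 states, got K={K}")
        for name in ("step_mean", "step_sd", "angle_conc"):
            v = getattr(self, name)
            if v.shape != (K,) or not np.all(v > 0):
                raise ValueError(f"{name} must be a positive length-{K} vector")
        if self.angle_mean.shape != (K,):
            raise ValueError("angle_mean has wrong length")
        if np.any(self.angle_mean <= -np.pi) or np.any(self.angle_mean > np.pi):
            raise ValueError("angle_mean must lie in (-pi, pi]")
        if np.any(self.zero_mass < 0) or np.any(self.zero_mass >= 1):
            raise ValueError("zero_mass must lie in [0, 1)")
        if self.beta.shape[1] != K * (K - 1):
            raise ValueError(
                f"beta must have K(K-1)={K * (K - 1)} columns, got {self.beta.shape[1]}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta entries must be finite")
        if self.delta.shape != (K,) or np.any(self.delta < 0):
            raise ValueError("delta must be a non-negative length-K vector")
        if abs(self.delta.sum() - 1.0) > 1e-8:
            raise ValueError("delta must sum to 1")

    def permute(self, order: np.ndarray) -> "HMMParameters":
        """Relabel states: new state s is old state ``order[s]``."""
        order = np.asarray(order, int)
        K = self.n_states
        pairs = transition_pairs(K)
        col_of = {p: c for c, p in enumerate(pairs)}
        new_cols = [col_of[(order[i], order[j])] for (i, j) in pairs]
        return HMMParameters(
            step_mean=self.step_mean[order],
            step_sd=self.step_sd[order],
            zero_mass=self.zero_mass[order],
            angle_mean=self.angle_mean[order],
            angle_conc=self.angle_conc[order],
            beta=self.beta[:, new_cols],
            delta=self.delta[order],
        )

    def to_dict(self) -> dict:
        return {
            "step_mean": self.step_mean.tolist(),
            "step_sd": self.step_sd.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "angle_mean": self.angle_mean.tolist(),
            "angle_conc": self.angle_conc.tolist(),
            "beta": self.beta.tolist(),
            "delta": self.delta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        return cls(
            step_mean=np.array(d["step_mean"], float),
            step_sd=np.array(d["step_sd"], float),
            zero_mass=np.array(d["zero_mass"], float),
            angle_mean=np.array(d["angle_mean"], float),
            angle_conc=np.array(d["angle_conc"], float),
            beta=np.array(d["beta"], float),
            delta=np.array(d["delta"], float),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class StepAngleSeries:
    """Aligned step lengths, turning angles and design rows for >= 1 bursts.

    Bursts are stacked; ``lengths[b]`` gives the number of steps of burst
    ``b``.  Missing observations are NaN.  The design matrix must contain
    an intercept column of ones as its first column.
    """

    steps: np.ndarray
    angles: np.ndarray
    design: np.ndarray
    lengths: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, float).ravel()
        self.angles = np.asarray(self.angles, float).ravel()
        self.design = np.atleast_2d(np.asarray(self.design, float))
        self.lengths = np.asarray(self.lengths, int).ravel()
        T = self.steps.size
        if self.angles.size != T or self.design.shape[0] != T:
            raise ValueError("steps, angles and design must have equal length")
        if self.lengths.sum() != T:
            raise ValueError("lengths must sum to the number of steps")
        if np.any(self.lengths < 1):
            raise ValueError("every burst must contain at least one step")
        if T and not np.allclose(self.design[:, 0], 1.0):
            raise ValueError("design must start with an intercept column of ones")
        if not self.feature_names:
            self.feature_names = ["intercept"] + [
                f"x{i}" for i in range(1, self.design.shape[1])
            ]

    @classmethod
    def from_bursts(
        cls,
        steps: list[np.ndarray],
        angles: list[np.ndarray],
        design: list[np.ndarray],
        feature_names: list[str] | None = None,
    ) -> "StepAngleSeries":
        lengths = np.array([len(s) for s in steps], int)
        return cls(
            steps=np.concatenate(steps) if steps else np.empty(0),
            angles=np.concatenate(angles) if angles else np.empty(0),
            design=np.vstack(design) if design else np.empty((0, 1)),
            lengths=lengths,
            feature_names=feature_names or [],
        )

    @property
    def n_steps(self) -> int:
        return self.steps.size

    @property
    def n_bursts(self) -> int:
        return self.lengths.size

    @property
    def n_obs(self) -> int:
        """Number of non-missing step observations (the BIC sample size)."""
        return int(np.sum(~np.isnan(self.steps)))

    def subset_design(self, columns: list[str]) -> "StepAngleSeries":
        """Return a copy restricted to the named design columns."""
        idx = [self.feature_names.index(c) for c in columns]
        return StepAngleSeries(
            steps=self.steps.copy(),
            angles=self.angles.copy(),
            design=self.design[:, idx].copy(),
            lengths=self.lengths.copy(),
            feature_names=list(columns),
        )

    def burst_slices(self) -> list[slice]:
        stops = np.cumsum(self.lengths)
        starts = np.concatenate([[0], stops[:-1]])
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]
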