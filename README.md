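# movestates

Inference of behavioural states (resting, foraging, relocating) from
regular hourly GPS tracks with covariate-driven hidden Markov models, and
the behavioural summaries used to evaluate foraging strategies in
strongly seasonal environments: activity budgets, bout durations and
covariate-conditional state-occupancy curves.

The package is aimed at movement ecologists working with telemetry data
from large herbivores (the canonical use case is year-round tracking of
high-arctic muskoxen), but nothing in it is species-specific: any
regularly sampled planar track with per-fix environmental covariates
fits.

## The model

Hourly step lengths `l_t` and turning angles `theta_t` are modelled as a
bivariate hidden Markov model with K latent behavioural states.
Conditional on state i,

* `l_t ~ Gamma(mean mu_i, sd sigma_i)`, optionally with a point mass
  `zeta_i` at exactly zero,
* `theta_t ~ von Mises(phi_i, kappa_i)`,

and the state sequence follows a Markov chain whose transition matrix
`Gamma(t)` depends on per-step covariates `z_t` through a multinomial
logit with the self-transition as reference category:

```
eta_ij(t) = z_t' beta_(i->j)          (j != i), eta_ii = 0
Gamma_ij(t) = exp(eta_ij(t)) / sum_k exp(eta_ik(t))
```

Estimation maximises the scaled forward log-likelihood over all bursts
jointly, from 30 random starting values by default; states are labelled
by ascending mean step length (resting < foraging < relocating).  Model
building uses BIC forward selection over candidate covariate blocks
(sin/cos pairs for cyclic covariates such as time of day, dummy sets for
categorical ones).  Decoding uses the Viterbi algorithm; long-run state
occupancy at covariate value x is summarised by the stationary
distribution of `Gamma(x)` with pointwise 95% Monte Carlo confidence
bands drawn from the estimator's approximate multivariate normal
distribution; goodness of fit uses one-step-ahead pseudo-residuals.

Everything is organised as scikit-learn style estimators —
`MovementHMM` (fit / predict / predict_proba / score), `DesignEncoder`
(fit / transform) and `ForwardBICSelector` — with thin functional
wrappers, plus a `movestates` command-line interface
(`simulate / preprocess / fit / select / decode / summarise`) driven by
one YAML config.

## Worked example

```python
import numpy as np
from movestates.simulate import default_scenario, simulate_tracks
from movestates.preprocessing import split_bursts, bursts_to_series
from movestates.hmm import MovementHMM

scenario = default_scenario(n_animals=2, n_hours=2001, seed=42)
bursts = [b for s in simulate_tracks(scenario) for b in split_bursts(s.track)]
series = bursts_to_series(bursts, scenario.encoder())

model = MovementHMM(n_states=3, n_starts=10, random_state=1).fit(series)
print(f"logL = {model.log_likelihood_:.1f}, BIC = {model.bic_:.1f}")
print("step means (m):", np.round(model.params_.step_mean, 1))
print("angle concentrations:", np.round(model.params_.angle_conc, 2))
states = model.predict(series)
print("decoded budget:", np.round(np.bincount(states)[1:] / states.size, 3))
```

prints (exactly, given the seeds):

```
logL = -29932.2, BIC = 60179.5
step means (m): [ 20.5 177.8 594. ]
angle concentrations: [1.1  0.8  3.96]
decoded budget: [0.378 0.304 0.318]
```

The three fitted states recover the generative emission scales (short
undirected resting steps around 20 m/h, tortuous foraging steps around
180 m/h, directed relocation steps around 600 m/h); the decoded budget
is the share of hours assigned to each state by the Viterbi sequence.

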