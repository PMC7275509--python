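"""BIC-based forward covariate selection and state-number comparison.

Candidate covariates enter the transition model in *blocks* (sin/cos pair
for a cyclic covariate, the dummy set for a categorical one, a single
column for a continuous one), added to all K(K-1) transition predictors
simultaneously.  Starting from the intercept-only transition model, each
round fits one model per remaining block and adopts the block with the
lowest BIC if it improves on the incumbent; selection stops when no block
improves.  Ties are broken by the declared block order.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import StepAngleSeries
from .design import CandidateBlock
from .hmm import HMMFitError, MovementHMM

__all__ = ["bic", "ForwardBICSelector", "forward_select", "compare_state_numbers"]


def bic(log_likelihood: float, n_parameters: int, n_obs: int) -> float:
    """Bayesian Information Criterion, -2 logL + k ln(n); lower is better."""
    if n_obs < 0 or n_parameters < 0:
        raise ValueError("n_obs and n_parameters must be non-negative")
    penalty = 0.0 if n_parameters == 0 else n_parameters * math.log(n_obs)
    return -2.0 * log_likelihood + penalty


class ForwardBICSelector(BaseEstimator):
    """Forward BIC selection over candidate covariate blocks.

    Parameters
    ----------
    blocks : list of CandidateBlock
        Candidate covariates; each block's ``columns`` must exist in the
        series' design feature names.
    n_states : int, default 3
    n_starts : int, default 5
        Random starts per selection-round fit (reduced-cost mode); the
        final model is refitted with ``final_n_starts``.
    final_n_starts : int, default 30
    random_state : int or None

    Attributes
    ----------
    path_ : DataFrame with one row per adopted block (block, bic_before,
        bic_after)
    report_ : DataFrame logging every fitted candidate model
    selected_blocks_ : list of adopted block names in adoption order
    best_model_ : the final refitted :class:`MovementHMM`
    """

    def __init__(
        self,
        blocks: list[CandidateBlock],
        n_states: int = 3,
        n_starts: int = 5,
        final_n_starts: int = 30,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.blocks = blocks
        self.n_states = n_states
        self.n_starts = n_starts
        self.final_n_starts = final_n_starts
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit_one(self, series, columns, n_starts, seed, hessian=False, warm=None):
        from .hmm import moment_start

        sub = series.subset_design(columns)
        # every fit gets a deterministic moment-based start alongside the
        # random ones (and the incumbent warm start during rounds): BIC
        # comparisons are only as reliable as each fit's optimum
        starts = [] if warm is None else [warm]
        if not np.any(sub.steps == 0.0):
            try:
                starts.append(moment_start(sub, self.n_states))
            except ValueError:
                pass
        model = MovementHMM(
            n_states=self.n_states,
            n_starts=max(n_starts, len(starts)),
            compute_hessian=hessian,
            max_iter=self.max_iter,
            random_state=seed,
            initial_params=starts or None,
        )
        return model.fit(sub)

    @staticmethod
    def _warm_vector(incumbent: MovementHMM, n_new_columns: int) -> np.ndarray:
        """Extend the incumbent's working vector with zero slopes for the
        design columns a candidate block appends (beta rows are the last
        working block, so zeros are appended)."""
        K = incumbent.params_.n_states
        return np.concatenate(
            [incumbent.working_params_, np.zeros(n_new_columns * K * (K - 1))]
        )

    def fit(self, X: StepAngleSeries, y=None):
        series = X
        if not isinstance(series, StepAngleSeries):
            raise TypeError("forward selection needs a StepAngleSeries")
        for b in self.blocks:
            unknown = [c for c in b.columns if c not in series.feature_names]
            if unknown:
                raise ValueError(f"block {b.name!r} refers to unknown columns {unknown}")
        ss = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        seeds = iter(ss.generate_state(10_000) % (2**31))

        current_cols = ["intercept"]
        # the base model anchors every later BIC comparison, so give it a
        # few extra starts: a locally-optimal incumbent would make inert
        # blocks look informative
        incumbent = self._fit_one(
            series, current_cols, max(self.n_starts, 8), int(next(seeds))
        )
        incumbent_bic = incumbent.bic_
        remaining = list(self.blocks)
        path_rows, log_rows = [], []
        log_rows.append(
            {"round": 0, "block": "(intercept only)", "bic": incumbent_bic,
             "loglik": incumbent.log_likelihood_, "adopted": True}
        )
        rnd = 0
        while remaining:
            rnd += 1
            cand = []
            for blk in remaining:
                try:
                    fit = self._fit_one(
                        series,
                        current_cols + blk.columns,
                        self.n_starts,
                        int(next(seeds)),
                        warm=self._warm_vector(incumbent, len(blk.columns)),
                    )
                    cand.append((blk, fit))
                    log_rows.append(
                        {"round": rnd, "block": blk.name, "bic": fit.bic_,
                         "loglik": fit.log_likelihood_, "adopted": False}
                    )
                except HMMFitError:
                    log_rows.append(
                        {"round": rnd, "block": blk.name, "bic": np.nan,
                         "loglik": np.nan, "adopted": False}
                    )
            if not cand:
                raise HMMFitError(f"all candidate fits failed in round {rnd}")
            bics = [f.bic_ for _, f in cand]
            best_idx = int(np.argmin(bics))  # first minimum: declared order wins ties
            best_blk, best_fit = cand[best_idx]
            if best_fit.bic_ < incumbent_bic:
                path_rows.append(
                    {"block": best_blk.name, "bic_before": incumbent_bic,
                     "bic_after": best_fit.bic_}
                )
                log_rows[-len(cand) + best_idx]["adopted"] = True
                current_cols = current_cols + best_blk.columns
                incumbent, incumbent_bic = best_fit, best_fit.bic_
                remaining = [b for b in remaining if b.name != best_blk.name]
            else:
                break

        self.selected_blocks_ = [r["block"] for r in path_rows]
        self.selected_columns_ = list(current_cols)
        self.path_ = pd.DataFrame(
            path_rows, columns=["block", "bic_before", "bic_after"]
        )
        self.report_ = pd.DataFrame(log_rows)
        # final refit at full strength, with the estimator covariance
        self.best_model_ = self._fit_one(
            series,
            current_cols,
            self.final_n_starts,
            int(next(seeds)),
            hessian=True,
            warm=incumbent.working_params_,
        )
        return self


def forward_select(
    series: StepAngleSeries,
    blocks: list[CandidateBlock],
    n_states: int = 3,
    n_starts: int = 5,
    final_n_starts: int = 30,
    seed: int | None = None,
) -> ForwardBICSelector:
    """Functional wrapper over :class:`ForwardBICSelector`."""
    return ForwardBICSelector(
        blocks,
        n_states=n_states,
        n_starts=n_starts,
        final_n_starts=final_n_starts,
        random_state=seed,
    ).fit(series)


def compare_state_numbers(
    series: StepAngleSeries,
    k_range=(2, 3, 4, 5),
    n_starts: int = 30,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one model per state number and tabulate (K, logL, k, BIC).

    No automatic choice is made: BIC tends to favour ever-larger state
    numbers on real movement data, so the table is reported and the user
    picks K on interpretability grounds.  Fit failures are recorded per K
    and do not abort the remaining fits.
    """
    rows = []
    for i, K in enumerate(sorted(k_range)):
        if K < 2:
            raise ValueError("state numbers below 2 are not supported")
        sub_seed = None if seed is None else seed + 1000 * i
        try:
            m = MovementHMM(
                n_states=K,
                n_starts=n_starts,
                compute_hessian=False,
                random_state=sub_seed,
                **fit_kwargs,
            ).fit(series)
            rows.append(
                {"n_states": K, "loglik": m.log_likelihood_,
                 "n_parameters": m.n_parameters_, "bic": m.bic_,
                 "converged": m.converged_, "error": ""}
            )
        except (HMMFitError, ValueError) as exc:
            rows.append(
                {"n_states": K, "loglik": np.nan, "n_parameters": np.nan,
                 "bic": np.nan, "converged": False, "error": str(exc)}
            )
    return pd.DataFrame(rows).sort_values("n_states").reset_index(drop=True)
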