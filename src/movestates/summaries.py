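"""Behavioural summaries from decoded state sequences.

Activity budgets (share of time in each state, reported as the
cross-individual mean with the min-max range), bout durations
(run lengths of identical decoded states, in hours), and the pairwise
proximity screen used to justify treating individuals as independent.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .solar import light_season

__all__ = [
    "STATE_NAMES",
    "activity_budget",
    "bout_durations",
    "mean_bout_durations",
    "proximity_fraction",
    "attach_light_season",
]

logger = logging.getLogger(__name__)

STATE_NAMES = {1: "resting", 2: "foraging", 3: "relocating"}


def activity_budget(
    decoded: pd.DataFrame,
    by: list[str] | None = None,
    state_col: str = "state",
    animal_col: str = "animal_id",
) -> pd.DataFrame:
    """Cross-individual activity budget per group and state.

    ``decoded`` needs one row per decoded hourly step with the animal id,
    the state label and any grouping columns (month, landcover, ...).
    Within each group the per-individual proportions of steps in each
    state are computed first (they sum to exactly 1 per individual), then
    summarised across individuals as mean, min, max and the number of
    individuals, matching the "mean [range]" reporting convention.
    """
    by = list(by or [])
    df = decoded.dropna(subset=[state_col])
    if df.empty:
        raise ValueError("no decoded states to summarise")
    states = np.sort(df[state_col].unique())
    counts = (
        df.groupby(by + [animal_col, state_col], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    # complete the per-individual state table so absent states count as 0
    keys = counts[by + [animal_col]].drop_duplicates()
    full = keys.merge(pd.DataFrame({state_col: states}), how="cross")
    counts = full.merge(counts, on=by + [animal_col, state_col], how="left").fillna(
        {"n": 0}
    )
    totals = counts.groupby(by + [animal_col], observed=True)["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    out = (
        counts.groupby(by + [state_col], observed=True)["proportion"]
        .agg(mean="mean", min="min", max="max", n_individuals="size")
        .reset_index()
    )
    out["state_name"] = out[state_col].map(STATE_NAMES).fillna("")
    return out


def bout_durations(
    decoded: pd.DataFrame,
    state_col: str = "state",
    animal_col: str = "animal_id",
    burst_col: str = "burst_id",
    time_col: str = "timestamp",
    include_censored: bool = True,
) -> pd.DataFrame:
    """Run-length encode decoded sequences into behavioural bouts.

    A bout is a maximal run of identical states within one burst; its
    duration is the run length in hours and it is assigned to the month
    containing its first step.  Bouts truncated by a burst boundary are
    flagged censored and included by default (dropping them would bias
    long bouts downward).
    """
    rows = []
    for (animal, burst), g in decoded.groupby([animal_col, burst_col], sort=False):
        s = g[state_col].to_numpy()
        ts = pd.to_datetime(g[time_col]).to_numpy()
        n = len(s)
        if n == 0:
            continue
        change = np.flatnonzero(s[1:] != s[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n]])
        for a, b in zip(starts, ends):
            rows.append(
                {
                    animal_col: animal,
                    burst_col: burst,
                    "state": s[a],
                    "start": ts[a],
                    "month": pd.Timestamp(ts[a]).month,
                    "duration_h": float(b - a),
                    "censored": a == 0 or b == n,
                }
            )
    bouts = pd.DataFrame(rows)
    if not include_censored and not bouts.empty:
        bouts = bouts[~bouts["censored"]].reset_index(drop=True)
    return bouts


def mean_bout_durations(
    bouts: pd.DataFrame, animal_col: str = "animal_id"
) -> pd.DataFrame:
    """Individual-based mean bout duration per month and state."""
    per_ind = (
        bouts.groupby([animal_col, "month", "state"], observed=True)["duration_h"]
        .mean()
        .reset_index()
    )
    out = (
        per_ind.groupby(["month", "state"], observed=True)["duration_h"]
        .agg(mean="mean", min="min", max="max", n_individuals="size")
        .reset_index()
    )
    out["state_name"] = out["state"].map(STATE_NAMES).fillna("")
    return out


def proximity_fraction(
    tracks: pd.DataFrame,
    threshold: float = 100.0,
    animal_col: str = "animal_id",
    time_col: str = "timestamp",
    by: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Share of simultaneous fixes with two animals closer than ``threshold``.

    For every animal pair and every common timestamp where both positions
    are present, the Euclidean distance is compared (strictly) against
    the threshold.  Returns the per-pair table and the cross-pair mean
    and range of the percentage, optionally per grouping column (e.g.
    season).
    """
    by = list(by or [])
    animals = sorted(tracks[animal_col].unique())
    if len(animals) < 2:
        raise ValueError("proximity analysis needs at least two animals")
    cols = [time_col, "x", "y"] + by
    rows = []
    for a, b in itertools.combinations(animals, 2):
        ta = tracks.loc[tracks[animal_col] == a, cols].dropna(subset=["x", "y"])
        tb = tracks.loc[tracks[animal_col] == b, cols].dropna(subset=["x", "y"])
        merged = ta.merge(tb, on=[time_col] + by, suffixes=("_a", "_b"))
        if merged.empty:
            logger.info("pair (%s, %s) has no simultaneous fixes; omitted", a, b)
            continue
        close = (
            np.hypot(
                merged["x_a"] - merged["x_b"], merged["y_a"] - merged["y_b"]
            )
            < threshold
        )
        if by:
            for key, g in merged.groupby(by, observed=True):
                key = key if isinstance(key, tuple) else (key,)
                sel = close.loc[g.index]
                rows.append(
                    dict(zip(by, key))
                    | {"animal_a": a, "animal_b": b, "n_shared": len(g),
                       "percent_close": 100.0 * sel.mean()}
                )
        else:
            rows.append(
                {"animal_a": a, "animal_b": b, "n_shared": len(merged),
                 "percent_close": 100.0 * close.mean()}
            )
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ValueError("no animal pair shares any timestamps")
    summary_keys = by if by else []
    if summary_keys:
        agg = pairs.groupby(summary_keys)["percent_close"].agg(
            ["mean", "min", "max"]
        )
        summary = {str(k): v.to_dict() for k, v in agg.iterrows()}
    else:
        summary = {
            "mean": float(pairs["percent_close"].mean()),
            "min": float(pairs["percent_close"].min()),
            "max": float(pairs["percent_close"].max()),
        }
    return pairs, summary


def attach_light_season(
    decoded: pd.DataFrame,
    lat: float,
    lon: float,
    time_col: str = "timestamp",
) -> pd.DataFrame:
    """Add the four-level light-season label used for diel budget panels."""
    out = decoded.copy()
    out["light_season"] = light_season(lat, lon, out[time_col])
    return out
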