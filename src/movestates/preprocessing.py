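"""Raw hourly GPS relocations -> regular seasonal bursts -> model series.

The processing chain mirrors standard practice for telemetry HMMs:

1. regularise each animal's fixes onto an hourly grid and split at
   observation gaps longer than 10 h (shorter gaps stay as missing
   positions inside the burst),
2. cut bursts into snow-free ("summer") and snow-covered ("winter")
   sections using 48 h snow-free runs,
3. drop seasonal bursts shorter than 4 full weeks (672 h),
4. fill missing covariate values (linear interpolation for continuous,
   nearest-with-earlier-tie for categorical),
5. compute step lengths and turning angles between consecutive fixes.

Tracks and bursts are pandas DataFrames; burst metadata (animal, burst
id, season) travels in ``DataFrame.attrs``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import StepAngleSeries
from .design import DesignEncoder

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "split_bursts",
    "assign_seasons",
    "filter_bursts",
    "compute_steps_angles",
    "interpolate_covariates",
    "check_collinearity",
    "flag_impossible_movements",
    "bursts_to_series",
    "MIN_BURST_HOURS",
]

MIN_BURST_HOURS = 672  # 4 full weeks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_track_csv(path) -> pd.DataFrame:
    """Read the track CSV dialect: id, timestamp (ISO 8601), x, y, covariates."""
    df = pd.read_csv(path, comment="#")
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_track_csv(df: pd.DataFrame, path, header_lines: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# burst construction
# ---------------------------------------------------------------------------

def _check_hourly(ts: pd.Series, tol_seconds: float = 60.0):
    if ts.duplicated().any():
        raise ValueError("duplicate timestamps in track")
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted increasingly")
    frac = (ts - ts.dt.floor("h")).dt.total_seconds()
    off = np.minimum(frac, 3600.0 - frac)
    if np.any(off > tol_seconds):
        raise ValueError(
            "timestamps deviate from the hourly grid by more than the tolerance"
        )


def split_bursts(
    track: pd.DataFrame, max_gap_hours: int = 10, tol_seconds: float = 60.0
) -> list[pd.DataFrame]:
    """Split one animal's track at observation gaps exceeding ``max_gap_hours``.

    The gap length is the number of missing hourly positions between two
    obtained fixes (fixes 11 h apart = a 10 h gap).  Gaps up to the
    threshold are retained as missing-position rows on the hourly grid;
    longer gaps start a new burst.
    """
    if track.empty:
        return []
    if track["animal_id"].nunique() > 1:
        raise ValueError("split_bursts expects a single animal's track")
    track = track.copy()
    _check_hourly(track["timestamp"], tol_seconds)
    track["timestamp"] = track["timestamp"].dt.round("h")
    present = track.dropna(subset=["x", "y"])
    if present.empty:
        return []
    gaps_h = present["timestamp"].diff().dt.total_seconds().to_numpy() / 3600.0
    new_burst = np.zeros(len(present), bool)
    new_burst[0] = True
    new_burst[1:] = gaps_h[1:] - 1.0 > max_gap_hours
    burst_no = np.cumsum(new_burst)
    bursts = []
    animal = track["animal_id"].iloc[0]
    for b in np.unique(burst_no):
        part = present.loc[burst_no == b]
        grid = pd.date_range(
            part["timestamp"].iloc[0], part["timestamp"].iloc[-1], freq="h"
        )
        full = (
            part.set_index("timestamp")
            .reindex(grid)
            .rename_axis("timestamp")
            .reset_index()
        )
        full["animal_id"] = animal
        full.attrs["animal_id"] = animal
        full.attrs["burst_id"] = f"{animal}-{b:02d}"
        bursts.append(full)
    return bursts


def assign_seasons(
    burst: pd.DataFrame,
    snow_encounter: np.ndarray | None = None,
    snow_col: str = "snow_depth",
    snow_threshold: float = 0.0,
    min_run_hours: int = 48,
) -> list[pd.DataFrame]:
    """Cut a burst into a summer section and surrounding winter sections.

    Summer is the contiguous interval from the start of the first
    ``min_run_hours`` snow-free run to the end of the last such run;
    everything else is winter.  "Snow encounter" defaults to snow depth
    above ``snow_threshold`` at the fix.
    """
    if snow_encounter is None:
        if snow_col not in burst.columns:
            raise ValueError(
                f"no snow-encounter series and no {snow_col!r} column available"
            )
        snow_encounter = (
            pd.to_numeric(burst[snow_col], errors="coerce").to_numpy()
            > snow_threshold
        )
    snow_encounter = np.asarray(snow_encounter, bool)
    n = len(burst)
    if snow_encounter.size != n:
        raise ValueError("snow encounter series not aligned with burst")
    free = ~snow_encounter
    # run-length encode the snow-free indicator
    run_start, run_len = [], []
    i = 0
    while i < n:
        if free[i]:
            j = i
            while j < n and free[j]:
                j += 1
            run_start.append(i)
            run_len.append(j - i)
            i = j
        else:
            i += 1
    long_runs = [
        (s, l) for s, l in zip(run_start, run_len) if l >= min_run_hours
    ]
    pieces = []
    if not long_runs:
        seasons = [("winter", 0, n)]
    else:
        lo = long_runs[0][0]
        hi = long_runs[-1][0] + long_runs[-1][1]
        seasons = []
        if lo > 0:
            seasons.append(("winter", 0, lo))
        seasons.append(("summer", lo, hi))
        if hi < n:
            seasons.append(("winter", hi, n))
    for k, (season, a, b) in enumerate(seasons):
        part = burst.iloc[a:b].reset_index(drop=True)
        part.attrs.update(burst.attrs)
        part.attrs["season"] = season
        part.attrs["burst_id"] = f"{burst.attrs.get('burst_id', 'b')}-{season[0]}{k}"
        pieces.append(part)
    return pieces


def filter_bursts(
    bursts: list[pd.DataFrame], min_weeks: int = 4
) -> tuple[list[pd.DataFrame], dict]:
    """Drop seasonal bursts shorter than ``min_weeks`` full weeks (672 h).

    Returns the retained bursts and a report of removal counts/fractions.
    """
    min_hours = int(min_weeks * 7 * 24)
    kept = [b for b in bursts if len(b) >= min_hours]
    n_obs_total = sum(int(b[["x", "y"]].notna().all(axis=1).sum()) for b in bursts)
    n_obs_kept = sum(int(b[["x", "y"]].notna().all(axis=1).sum()) for b in kept)
    report = {
        "n_input": len(bursts),
        "n_removed": len(bursts) - len(kept),
        "n_retained": len(kept),
        "min_hours": min_hours,
        "obs_input": n_obs_total,
        "obs_removed_fraction": (
            0.0 if n_obs_total == 0 else 1.0 - n_obs_kept / n_obs_total
        ),
    }
    return kept, report


# ---------------------------------------------------------------------------
# movement variables
# ---------------------------------------------------------------------------

def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    """Heuristic: values inside lon/lat bounds with degree-scale hourly
    displacements (anything below ~0.05 units/h would be absurd in metres)."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        return False
    in_bounds = (
        np.nanmax(np.abs(x[ok])) <= 180.0 and np.nanmax(np.abs(y[ok])) <= 90.0
    )
    if not in_bounds:
        return False
    disp = np.hypot(np.diff(x), np.diff(y))
    disp = disp[np.isfinite(disp)]
    return disp.size > 0 and float(np.median(disp)) < 0.05


def compute_steps_angles(burst: pd.DataFrame) -> pd.DataFrame:
    """Step lengths and turning angles on the burst's hourly grid.

    Step t is the Euclidean displacement between grid hours t and t+1
    (missing when either position is missing); the turning angle at step
    t is the signed heading change from step t-1 to step t, wrapped to
    (-pi, pi], counter-clockwise positive, missing whenever an adjacent
    displacement is missing or has zero length.  The first step of a
    burst has no turning angle.
    """
    x = burst["x"].to_numpy(float)
    y = burst["y"].to_numpy(float)
    if _looks_geographic(x, y) and len(burst) > 2:
        raise ValueError(
            "coordinates look like lon/lat degrees; project to planar metres first"
        )
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)
    angle = np.full(step.size, np.nan)
    if step.size > 1:
        turn = heading[1:] - heading[:-1]
        turn = np.mod(turn + np.pi, 2.0 * np.pi) - np.pi
        turn[turn == -np.pi] = np.pi  # wrap to (-pi, pi]
        ok = (
            np.isfinite(step[1:])
            & np.isfinite(step[:-1])
            & (step[1:] > 0)
            & (step[:-1] > 0)
        )
        angle[1:] = np.where(ok, turn, np.nan)
    out = pd.DataFrame(
        {
            "timestamp": burst["timestamp"].iloc[:-1].to_numpy(),
            "step": step,
            "angle": angle,
        }
    )
    out.attrs.update(burst.attrs)
    return out


def interpolate_covariates(
    burst: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Fill missing covariate values on the hourly grid.

    Continuous covariates: linear interpolation, edges padded with the
    nearest value.  Categorical covariates: nearest non-missing neighbour
    in time, earlier value on ties.
    """
    out = burst.copy()
    n = len(out)
    for col in continuous or []:
        v = pd.to_numeric(out[col], errors="coerce")
        if v.notna().sum() == 0:
            raise ValueError(f"covariate {col!r} is entirely missing")
        if v.notna().sum() == 1:
            out[col] = v.ffill().bfill()
            continue
        out[col] = v.interpolate(method="linear", limit_direction="both")
    for col in categorical or []:
        v = out[col]
        if v.notna().sum() == 0:
            raise ValueError(f"covariate {col!r} is entirely missing")
        idx = np.arange(n)
        known = idx[v.notna().to_numpy()]
        # nearest known index; np.searchsorted + comparison, earlier on tie
        pos = np.searchsorted(known, idx)
        left = known[np.clip(pos - 1, 0, known.size - 1)]
        right = known[np.clip(pos, 0, known.size - 1)]
        nearest = np.where(idx - left <= right - idx, left, right)
        out[col] = v.to_numpy()[nearest]
    return out


def check_collinearity(
    covariates: pd.DataFrame, threshold: float = 0.6
) -> pd.DataFrame:
    """All pairwise Pearson correlations among continuous covariates.

    Pairs with \\|r\\| >= threshold are flagged; the fitted models should
    not include both members of a flagged pair.
    """
    num = covariates.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least two continuous covariates")
    sd = num.std(ddof=0)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance column(s): {zero_var}")
    rows = []
    for a, b in itertools.combinations(num.columns, 2):
        r = float(num[a].corr(num[b]))
        rows.append({"cov_a": a, "cov_b": b, "r": r, "flagged": abs(r) >= threshold})
    return pd.DataFrame(rows)


def flag_impossible_movements(
    track: pd.DataFrame, v_max: float = 2.5
) -> np.ndarray:
    """Flag fixes implying a sustained speed above ``v_max`` m/s.

    A configurable stand-in for the upstream impossible-movement screen;
    off by default in the pipeline.  Returns a boolean mask over rows.
    """
    ts = track["timestamp"]
    dt = ts.diff().dt.total_seconds().to_numpy()
    dist = np.hypot(track["x"].diff().to_numpy(), track["y"].diff().to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = dist / dt
    flags = np.zeros(len(track), bool)
    flags[1:] = speed[1:] > v_max
    return flags


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def bursts_to_series(
    bursts: list[pd.DataFrame], encoder: DesignEncoder, refit_encoder: bool = True
) -> StepAngleSeries:
    """Movement variables + encoded design rows for a set of bursts.

    The design row of step t uses the covariates at the step's starting
    hour.  The encoder is fitted across all bursts jointly (season-wide
    standardisation) unless ``refit_encoder`` is False.
    """
    if not bursts:
        raise ValueError("no bursts supplied")
    all_cov = pd.concat(bursts, ignore_index=True)
    if refit_encoder:
        encoder.fit(all_cov)
    steps, angles, designs = [], [], []
    for b in bursts:
        sa = compute_steps_angles(b)
        design = encoder.transform(b.iloc[:-1])
        if not np.all(np.isfinite(design)):
            raise ValueError(
                "design matrix contains missing values; interpolate covariates "
                "before building the series"
            )
        steps.append(sa["step"].to_numpy())
        angles.append(sa["angle"].to_numpy())
        designs.append(design)
    return StepAngleSeries.from_bursts(
        steps, angles, designs, feature_names=list(encoder.feature_names_out_)
    )
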