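"""Burst construction, season assignment, movement variables, covariates."""

import numpy as np
import pandas as pd
import pytest

from movestates.design import DesignEncoder
from movestates.preprocessing import (
    assign_seasons,
    bursts_to_series,
    check_collinearity,
    compute_steps_angles,
    filter_bursts,
    flag_impossible_movements,
    interpolate_covariates,
    split_bursts,
)


def make_track(n=48, gaps=(), start="2014-01-01", animal="a1"):
    """Hourly track walking east 100 m per hour; ``gaps`` are (start, length)
    runs of dropped fixes."""
    ts = pd.date_range(start, periods=n, freq="h")
    df = pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": ts,
            "x": 100.0 * np.arange(n),
            "y": 0.0,
        }
    )
    drop = np.zeros(n, bool)
    for s, l in gaps:
        drop[s : s + l] = True
    return df[~drop].reset_index(drop=True)


class TestSplitBursts:
    def test_gapless_track_is_one_burst(self):
        bursts = split_bursts(make_track(30))
        assert len(bursts) == 1
        assert len(bursts[0]) == 30

    def test_gap_at_threshold_retained_as_missing(self):
        bursts = split_bursts(make_track(48, gaps=[(10, 10)]))
        assert len(bursts) == 1
        assert int(bursts[0]["x"].isna().sum()) == 10

    def test_gap_above_threshold_splits(self):
        bursts = split_bursts(make_track(48, gaps=[(10, 12)]))
        assert len(bursts) == 2
        assert len(bursts[0]) == 10
        assert len(bursts[1]) == 26

    def test_eleven_hour_gap_splits(self):
        assert len(split_bursts(make_track(48, gaps=[(10, 11)]))) == 2

    def test_splitting_is_idempotent(self):
        bursts = split_bursts(make_track(60, gaps=[(20, 3)]))
        again = split_bursts(bursts[0])
        assert len(again) == 1
        assert again[0][["timestamp", "x", "y"]].equals(
            bursts[0][["timestamp", "x", "y"]]
        )

    def test_unsorted_or_duplicate_timestamps_raise(self):
        t = make_track(10)
        with pytest.raises(ValueError):
            split_bursts(t.iloc[::-1])
        dup = pd.concat([t, t.iloc[[3]]]).sort_values("timestamp")
        with pytest.raises(ValueError):
            split_bursts(dup)


class TestSeasons:
    def _burst(self, snow):
        n = len(snow)
        b = make_track(n)
        b["snow_depth"] = np.asarray(snow, float)
        return b

    def test_all_snow_free_is_summer(self):
        out = assign_seasons(self._burst(np.zeros(100)))
        assert [p.attrs["season"] for p in out] == ["summer"]

    def test_all_snow_is_winter(self):
        out = assign_seasons(self._burst(np.full(100, 0.5)))
        assert [p.attrs["season"] for p in out] == ["winter"]

    def test_runs_below_48h_stay_winter(self):
        snow = np.full(200, 0.5)
        snow[50:97] = 0.0  # 47 h snow-free: one hour short of the rule
        out = assign_seasons(self._burst(snow))
        assert [p.attrs["season"] for p in out] == ["winter"]

    def test_summer_spans_first_to_last_long_run(self):
        snow = np.full(400, 0.5)
        snow[50:110] = 0.0  # 60 h run
        snow[200:260] = 0.0  # 60 h run, snow in between stays inside summer
        out = assign_seasons(self._burst(snow))
        seasons = [p.attrs["season"] for p in out]
        assert seasons == ["winter", "summer", "winter"]
        assert len(out[0]) == 50
        assert len(out[1]) == 210  # hours 50..259
        assert len(out[2]) == 140

    def test_partition_is_exact(self):
        snow = (np.sin(np.arange(500) / 30.0) > 0).astype(float)
        burst = self._burst(snow)
        out = assign_seasons(burst)
        assert sum(len(p) for p in out) == len(burst)
        recon = pd.concat(out, ignore_index=True)
        assert recon["timestamp"].equals(burst["timestamp"])

    def test_missing_snow_data_raises(self):
        with pytest.raises(ValueError):
            assign_seasons(make_track(100))


class TestFilterBursts:
    def test_boundary_at_four_weeks(self):
        short = make_track(671)
        exact = make_track(672)
        kept, report = filter_bursts([short, exact])
        assert len(kept) == 1
        assert len(kept[0]) == 672
        assert report["n_removed"] == 1

    def test_report_counts(self):
        bursts = [make_track(700)] * 7 + [make_track(100)] * 3
        kept, report = filter_bursts(bursts)
        assert report["n_input"] == 10
        assert report["n_removed"] == 3
        assert report["n_retained"] == 7 == len(kept)


class TestStepsAngles:
    def _series(self, xy):
        n = len(xy)
        b = make_track(n)
        b["x"] = [p[0] for p in xy]
        b["y"] = [p[1] for p in xy]
        return compute_steps_angles(b)

    def test_three_four_five(self):
        sa = self._series([(0, 0), (3, 4)])
        assert np.isclose(sa["step"].iloc[0], 5.0)

    def test_collinear_motion_zero_turn(self):
        sa = self._series([(0, 0), (1, 0), (2, 0)])
        assert np.isclose(sa["angle"].iloc[1], 0.0)
        assert np.isnan(sa["angle"].iloc[0])  # first step has no turn

    def test_left_turn_is_positive_half_pi(self):
        sa = self._series([(0, 0), (1, 0), (1, 1)])
        assert np.isclose(sa["angle"].iloc[1], np.pi / 2)

    def test_right_turn_is_negative(self):
        sa = self._series([(0, 0), (1, 0), (1, -1)])
        assert np.isclose(sa["angle"].iloc[1], -np.pi / 2)

    def test_reversal_maps_to_pi(self):
        sa = self._series([(0, 0), (1, 0), (0, 0)])
        assert np.isclose(sa["angle"].iloc[1], np.pi)

    def test_zero_step_blanks_adjacent_angles(self):
        sa = self._series([(0, 0), (1, 0), (1, 0), (2, 0), (3, 0)])
        assert sa["step"].iloc[1] == 0.0
        assert np.isnan(sa["angle"].iloc[1])
        assert np.isnan(sa["angle"].iloc[2])
        assert np.isclose(sa["angle"].iloc[3], 0.0)

    def test_missing_position_blanks_steps_and_angles(self):
        b = make_track(6)
        b.loc[2, ["x", "y"]] = np.nan
        sa = compute_steps_angles(b)
        assert np.isnan(sa["step"].iloc[1])
        assert np.isnan(sa["step"].iloc[2])
        assert np.isnan(sa["angle"].iloc[1])
        assert np.isnan(sa["angle"].iloc[3])

    def test_geographic_coordinates_rejected(self):
        b = make_track(10)
        b["x"] = np.linspace(-20, -19.9, 10)
        b["y"] = np.linspace(74, 74.01, 10)
        with pytest.raises(ValueError, match="planar"):
            compute_steps_angles(b)

    def test_round_trip_recovers_simulated_draws(self):
        from movestates.simulate import default_scenario, simulate_track

        sc = default_scenario(n_animals=1, n_hours=1001, seed=21)
        s = simulate_track(sc)
        sa = compute_steps_angles(s.track)
        assert np.allclose(sa["step"].to_numpy(), s.steps, rtol=1e-9)
        got = sa["angle"].to_numpy()
        ok = np.isfinite(s.angles)
        assert np.array_equal(np.isfinite(got), ok)
        assert np.allclose(got[ok], s.angles[ok], rtol=1e-9, atol=1e-9)


class TestInterpolation:
    def test_midpoint_fill(self):
        b = make_track(3)
        b["temp"] = [1.0, np.nan, 3.0]
        out = interpolate_covariates(b, continuous=["temp"])
        assert out["temp"].iloc[1] == 2.0

    def test_no_missing_is_unchanged(self):
        b = make_track(5)
        b["temp"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = interpolate_covariates(b, continuous=["temp"])
        assert out["temp"].tolist() == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_edges_padded_with_nearest(self):
        b = make_track(4)
        b["temp"] = [np.nan, 2.0, np.nan, np.nan]
        out = interpolate_covariates(b, continuous=["temp"])
        assert out["temp"].tolist() == [2.0, 2.0, 2.0, 2.0]

    def test_categorical_nearest_earlier_on_tie(self):
        b = make_track(4)
        b["lc"] = ["a", None, None, "b"]
        out = interpolate_covariates(b, categorical=["lc"])
        assert out["lc"].tolist() == ["a", "a", "b", "b"]

    def test_all_missing_raises(self):
        b = make_track(4)
        b["temp"] = np.nan
        with pytest.raises(ValueError):
            interpolate_covariates(b, continuous=["temp"])


class TestCollinearity:
    def test_self_and_negated_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        rep = check_collinearity(df)
        ab = rep[(rep.cov_a == "a") & (rep.cov_b == "b")].iloc[0]
        ac = rep[(rep.cov_a == "a") & (rep.cov_b == "c")].iloc[0]
        assert np.isclose(ab.r, 1.0) and ab.flagged
        assert np.isclose(ac.r, -1.0) and ac.flagged

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        rep = check_collinearity(df)
        assert not rep["flagged"].any()

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            check_collinearity(df)


def test_speed_screen_flags_fast_fixes():
    b = make_track(10)
    b.loc[5, "x"] += 50_000  # implies ~14 m/s over one hour
    flags = flag_impossible_movements(b, v_max=2.5)
    assert flags[5]
    assert flags.sum() >= 1


def test_bursts_to_series_counts_and_design(small_scenario):
    from movestates.simulate import simulate_track

    s = simulate_track(small_scenario)
    bursts = split_bursts(s.track)
    enc = DesignEncoder(small_scenario.design_spec)
    series = bursts_to_series(bursts, enc)
    # steps per burst = grid length - 1 for a gap-free burst
    assert series.n_steps == sum(len(b) - 1 for b in bursts)
    assert series.feature_names == ["intercept", "hour_sin", "hour_cos", "snow_depth"]
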