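import numpy as np
import pandas as pd
import pytest

from aeromig import (
    AtmosphericGrid,
    FlowParams,
    ProfileTimeSeries,
    collinearity_screen,
    ground_level_value,
    pair_weather,
    preferred_direction,
    read_atmosphere,
    tailwind_eq_airspeed,
    wind_mad,
    write_atmosphere,
)
from aeromig.atmosphere import AtmosphereError


def _grid(times, levels, gph, values: dict) -> AtmosphericGrid:
    """Build a grid table from per-(time, level) value functions."""
    rows = []
    for t in times:
        for lev, h in zip(levels, gph):
            row = {"time": t, "level_hPa": lev, "gph_m": h}
            for var in ("u_wind", "v_wind", "temp", "shum", "omega", "tke"):
                fn = values.get(var, lambda tt, hh: 0.0)
                row[var] = fn(t, h)
            rows.append(row)
    return AtmosphericGrid(pd.DataFrame(rows))


def _series(station, timestamps, heights) -> ProfileTimeSeries:
    rows = []
    for ts in timestamps:
        for h in heights:
            rows.append({"datetime": ts, "height": h, "eta": 11.0, "u": 0.0, "v": 0.0})
    return ProfileTimeSeries(station=station, data=pd.DataFrame(rows))


T0 = pd.Timestamp("2021-09-05T00:00:00Z")
T3 = pd.Timestamp("2021-09-05T03:00:00Z")


class TestPairWeather:
    def test_constant_field_reproduced(self, station):
        grid = _grid([T0, T3], [1000, 900], [100.0, 1000.0], {"temp": lambda t, h: 280.0})
        series = _series(station, [T0 + pd.Timedelta(hours=1)], [0.0, 400.0, 900.0])
        paired = pair_weather(series, grid)
        assert np.allclose(paired["temp"], 280.0)

    def test_two_stage_hand_interpolation(self, station):
        # time: 10 -> 16 over 3 h, sampled at 01:00 gives 12 at the lower level;
        # a second level is chosen so its time interpolation gives 20;
        # altitude: levels at 0 m and 1000 m, bin center 500 m -> (12+20)/2 = 16
        grid = _grid(
            [T0, T3],
            [1000, 900],
            [0.0, 1000.0],
            {
                "temp": lambda t, h: (10.0 if t == T0 else 16.0)
                if h == 0.0
                else (20.0 if t == T0 else 20.0)
            },
        )
        series = _series(station, [T0 + pd.Timedelta(hours=1)], [400.0])  # center 450
        paired = pair_weather(series, grid)
        # time interpolation at 01:00: lower level 12, upper level 20
        # altitude interpolation at 450 m: 12 + (20-12) * 0.45 = 15.6
        assert paired["temp"].iloc[0] == pytest.approx(15.6)

    def test_clamping_below_lowest_level(self, station):
        grid = _grid(
            [T0, T3], [1000, 900], [500.0, 1500.0], {"temp": lambda t, h: 280.0 + h}
        )
        series = _series(station, [T0 + pd.Timedelta(hours=1)], [0.0, 4900.0])
        paired = pair_weather(series, grid)
        # bin center 50 m < lowest level 500 m -> clamp to lowest-level value
        assert paired["temp"].iloc[0] == pytest.approx(780.0)
        # bin center 4950 m > highest level 1500 m -> clamp to highest
        assert paired["temp"].iloc[1] == pytest.approx(1780.0)

    def test_jointly_linear_field_exact(self, station):
        # a field linear in both time and height is reproduced exactly
        f = lambda t, h: 2.0 + 0.001 * h + 3.0 * ((t - T0) / pd.Timedelta(hours=3))
        grid = _grid([T0, T3], [1000, 950, 900], [100.0, 1000.0, 2500.0], {"u_wind": f})
        ts = T0 + pd.Timedelta(minutes=47)
        series = _series(station, [ts], [200.0, 1200.0, 2400.0])
        paired = pair_weather(series, grid)
        for _, row in paired.iterrows():
            assert row["u_wind"] == pytest.approx(f(ts, row["height"] + 50.0), abs=1e-9)

    def test_outside_time_span_missing(self, station):
        grid = _grid([T0, T3], [1000, 900], [100.0, 1000.0], {"temp": lambda t, h: 280.0})
        series = _series(station, [T3 + pd.Timedelta(hours=2)], [100.0])
        paired = pair_weather(series, grid)
        assert np.isnan(paired["temp"].iloc[0])

    def test_provenance_columns_present(self, station):
        grid = _grid([T0, T3], [1000, 900], [100.0, 1000.0], {"temp": lambda t, h: 1.0})
        series = _series(station, [T0 + pd.Timedelta(hours=1)], [100.0])
        paired = pair_weather(series, grid)
        assert paired["time_lo"].iloc[0] == T0 and paired["time_hi"].iloc[0] == T3


class TestTailwind:
    FP = FlowParams(airspeed=8.0, preferred_direction=0.0)  # north

    def test_calm_wind_zero(self):
        assert tailwind_eq_airspeed(0.0, 0.0, self.FP) == pytest.approx(0.0)

    def test_pure_tailwind_equals_wind(self):
        assert tailwind_eq_airspeed(0.0, 5.0, self.FP) == pytest.approx(5.0)

    def test_pure_crosswind_closed_form(self):
        # crosswind 5, airspeed 8: sqrt(64-25) - 8
        assert tailwind_eq_airspeed(5.0, 0.0, self.FP) == pytest.approx(
            np.sqrt(39.0) - 8.0
        )

    def test_pure_crosswind_vector_oracle(self):
        # oracle: heading rotated to cancel crosswind; gain along preferred
        # direction is the ground speed minus airspeed
        c = 5.0
        a = 8.0
        # heading (u,v) with u = -c cancels crosswind; |heading| = a
        v_head = np.sqrt(a**2 - c**2)
        ground_along = v_head + 0.0  # wind has no along-track component
        assert tailwind_eq_airspeed(c, 0.0, self.FP) == pytest.approx(ground_along - a)

    def test_infeasible_crosswind_missing(self):
        assert np.isnan(tailwind_eq_airspeed(9.0, 0.0, self.FP))

    def test_never_exceeds_wind_speed(self):
        rng = np.random.default_rng(2)
        u, v = rng.normal(0, 4, 500), rng.normal(0, 4, 500)
        assist = tailwind_eq_airspeed(u, v, self.FP)
        speed = np.hypot(u, v)
        ok = ~np.isnan(assist)
        assert np.all(assist[ok] <= speed[ok] + 1e-12)

    def test_equals_wind_speed_iff_pure_tailwind(self):
        assert tailwind_eq_airspeed(0.0, 7.0, self.FP) == pytest.approx(7.0)
        assert tailwind_eq_airspeed(1.0, 7.0, self.FP) < np.hypot(1.0, 7.0)

    def test_decreasing_in_crosswind_at_fixed_tailwind(self):
        vals = [tailwind_eq_airspeed(c, 3.0, self.FP) for c in (0.0, 2.0, 4.0, 6.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPreferredDirection:
    def test_single_direction(self):
        assert preferred_direction([45.0, 45.0], [1.0, 9.0]) == pytest.approx(45.0)

    def test_wraparound(self):
        d = preferred_direction([350.0, 10.0], [1.0, 1.0])
        assert d == pytest.approx(0.0, abs=1e-9) or d == pytest.approx(360.0, abs=1e-9)
        assert 0.0 <= d < 360.0

    def test_weighted_circular_mean(self):
        # arctan of weighted sine/cosine sums: atan2(1, 3) = 18.43°
        assert preferred_direction([0.0, 90.0], [3.0, 1.0]) == pytest.approx(
            np.degrees(np.arctan2(1.0, 3.0))
        )

    def test_weight_scaling_invariance(self):
        a = preferred_direction([10.0, 200.0, 340.0], [1.0, 2.0, 3.0])
        b = preferred_direction([10.0, 200.0, 340.0], [10.0, 20.0, 30.0])
        assert a == pytest.approx(b)

    def test_rotation_equivariance(self):
        tracks = np.array([10.0, 50.0, 90.0])
        w = np.array([1.0, 2.0, 3.0])
        base = preferred_direction(tracks, w)
        rotated = preferred_direction((tracks + 77.0) % 360.0, w)
        assert rotated == pytest.approx((base + 77.0) % 360.0)

    def test_empty_subset_errors(self):
        with pytest.raises(AtmosphereError):
            preferred_direction([np.nan], [1.0])


class TestGroundLevel:
    def test_closest_bin_with_tie_to_lower(self, station):
        # station at 80 m; centers 50 and 150 are 30 and 70 m away -> 50 m bin
        paired = pd.DataFrame(
            {
                "datetime": [T0] * 3,
                "height": [0.0, 100.0, 200.0],
                "temp": [300.0, 299.0, 298.0],
            }
        )
        out = ground_level_value(paired, "temp", station)
        assert out["temp_ground"].iloc[0] == 300.0

    def test_tie_resolves_to_lower_bin(self, station):
        from aeromig import StationConfig

        st = StationConfig("T", 5.0, -73.0, 100.0, -5.0)  # centers 50/150 equidistant
        paired = pd.DataFrame(
            {"datetime": [T0, T0], "height": [0.0, 100.0], "temp": [1.0, 2.0]}
        )
        assert ground_level_value(paired, "temp", st)["temp_ground"].iloc[0] == 1.0

    def test_single_bin(self, station):
        paired = pd.DataFrame({"datetime": [T0], "height": [4000.0], "temp": [250.0]})
        assert ground_level_value(paired, "temp", station)["temp_ground"].iloc[0] == 250.0


class TestCollinearityScreen:
    def test_perfect_correlation_drops_lower_priority(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        table = pd.DataFrame({"x": x, "y": 2 * x})
        assert collinearity_screen(table, priority=["x", "y"]) == ["x"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(0, 1, (1000, 4)), columns=list("abcd"))
        assert collinearity_screen(table, priority=list("abcd")) == list("abcd")

    def test_three_mutually_correlated_keep_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        table = pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.1, 200), "c": -x + rng.normal(0, 0.1, 200)}
        )
        assert collinearity_screen(table, priority=["a", "b", "c"]) == ["a"]

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"a": rng.normal(0, 1, 20), "k": 5.0, "b": rng.normal(0, 1, 20)})
        assert collinearity_screen(table, priority=["a", "k", "b"]) == ["a", "b"]


class TestWindMad:
    def _records(self, speeds):
        return pd.DataFrame(
            {
                "time": pd.to_datetime(["2021-01-01", "2021-01-02"][: len(speeds)]),
                "height_m": [500.0] * len(speeds),
                "speed_ms": speeds,
            }
        )

    def test_identical_series_zero(self):
        a = self._records([3.0, 7.0])
        assert wind_mad(a, a.copy()) == 0.0

    def test_hand_mean(self):
        assert wind_mad(self._records([3.0, 7.0]), self._records([5.0, 5.0])) == 2.0

    def test_symmetry(self):
        a, b = self._records([3.0, 7.0]), self._records([5.0, 5.0])
        assert wind_mad(a, b) == wind_mad(b, a)

    def test_no_overlap_errors(self):
        a = self._records([3.0])
        b = self._records([5.0])
        b["time"] = pd.to_datetime(["2022-01-01"])
        with pytest.raises(AtmosphereError):
            wind_mad(a, b)


def test_atmosphere_round_trip(tmp_path):
    grid = _grid(
        [T0, T3],
        [1000, 900],
        [100.0, 1000.0],
        {"u_wind": lambda t, h: h / 100.0, "temp": lambda t, h: 280.0},
    )
    path = tmp_path / "atmo.csv"
    write_atmosphere(grid, path)
    back = read_atmosphere(path)
    pd.testing.assert_frame_equal(back.data, grid.data, check_exact=False)


def test_gph_monotonicity_enforced():
    with pytest.raises(AtmosphereError):
        _grid([T0], [1000, 900], [1000.0, 100.0], {})
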