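"""Daily means, wall duplication, Sibson interpolation, period stacks,
validation metrics and disturbance-recovery detection."""

import numpy as np
import pandas as pd
import pytest

from speleosdm import microclimate as mc
from speleosdm.cave_geometry import GeometryError


def _hourly_series(values, start="2015-01-01", **kw):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return mc.LoggerSeries("L0", "s0", 1, idx, np.asarray(values, float), 0.1, **kw)


class TestActivityPeriods:
    def test_months_disjoint_and_cover_activity_season(self):
        all_months = set()
        for p in mc.PERIODS:
            assert not (all_months & p.months)
            all_months |= p.months
        # Sep-May; summer (Jun-Aug) falls outside the bat activity periods
        assert all_months == set(range(1, 13)) - {6, 7, 8}

    def test_codes(self):
        assert mc.SO.months == frozenset({9, 10})
        assert mc.NM.months == frozenset({11, 12, 1, 2, 3})
        assert mc.AM.months == frozenset({4, 5})
        with pytest.raises(ValueError):
            mc.ActivityPeriod("XX")


class TestDailyMeans:
    def test_constant_day(self):
        s = _hourly_series([8.0] * 24)
        means, excluded = mc.compute_daily_means(s)
        assert means.iloc[0] == 8.0 and not excluded

    def test_hourly_ramp_mean(self):
        s = _hourly_series(list(range(24)))
        means, _ = mc.compute_daily_means(s)
        assert means.iloc[0] == pytest.approx(11.5)  # arithmetic-mean oracle

    def test_low_coverage_day_excluded(self):
        idx = pd.date_range("2015-01-01", periods=36, freq="h")
        # day 2 has only 12 of 24 hours
        s = mc.LoggerSeries("L0", "s0", 1, idx, np.full(36, 5.0), 0.1)
        means, excluded = mc.compute_daily_means(s)
        assert len(means) == 1 and len(excluded) == 1

    def test_timestamp_and_range_invariants(self):
        idx = pd.date_range("2015-01-01", periods=24, freq="h")
        with pytest.raises(ValueError, match="increasing"):
            mc.LoggerSeries("L", "s", 1, idx[[0] * 24], np.zeros(24), 0.1)
        with pytest.raises(ValueError, match="physical range"):
            mc.LoggerSeries("L", "s", 1, idx, np.full(24, 80.0), 0.1)


class TestWallDuplication:
    def test_triples_the_point_set_with_same_values(self, corridor_level):
        pts = np.array([[20.0, 1.0], [40.0, 1.0], [60.0, 1.0], [80.0, 1.0]])
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        p3, v3, src = mc.duplicate_points_to_walls(pts, vals, corridor_level)
        assert len(p3) == 12
        np.testing.assert_array_equal(v3, vals[src])

    def test_duplicates_perpendicular_to_ew_corridor(self, corridor_level):
        pts = np.array([[50.0, 1.0]])
        p3, _, _ = mc.duplicate_points_to_walls(pts, np.array([7.0]), corridor_level, 0.25)
        dups = p3[1:]
        # due north and due south, just outside the walls y=0 and y=2
        assert np.allclose(dups[:, 0], 50.0, atol=1e-9)
        assert sorted(dups[:, 1]) == pytest.approx([-0.25, 2.25])

    def test_point_outside_rejected(self, corridor_level):
        with pytest.raises(GeometryError, match="point outside cave"):
            mc.duplicate_points_to_walls(
                np.array([[50.0, 5.0]]), np.array([1.0]), corridor_level
            )


@pytest.fixture(scope="module")
def two_logger_field(corridor_level, corridor_grid):
    pts = np.array([[5.0, 1.0], [95.0, 1.0]])
    vals = np.array([4.0, 8.0])
    p3, v3, _ = mc.duplicate_points_to_walls(pts, vals, corridor_level)
    w = mc.sibson_weights(p3, corridor_grid)
    return p3, v3, w


class TestSibsonInterpolation:
    def test_constant_field_reproduced(self, corridor_grid, two_logger_field):
        p3, _, w = two_logger_field
        f = mc.interpolate_field(p3, np.full(len(p3), 9.3), corridor_grid, weights=w)
        inside = f.values[corridor_grid.inside_mask]
        np.testing.assert_allclose(inside, 9.3, atol=1e-9)

    def test_value_reproduced_at_data_point(self, corridor_grid, two_logger_field):
        p3, v3, w = two_logger_field
        f = mc.interpolate_field(p3, v3, corridor_grid, weights=w)
        r, c = corridor_grid.xy_to_rc(5.0, 1.0)
        assert f.values[r, c] == pytest.approx(4.0, abs=1e-6)

    def test_two_logger_linear_limit(self, corridor_grid, two_logger_field):
        p3, v3, w = two_logger_field
        f = mc.interpolate_field(p3, v3, corridor_grid, weights=w)
        r, c = corridor_grid.xy_to_rc(50.0, 1.0)
        assert f.values[r, c] == pytest.approx(6.0, abs=0.2)

    def test_bounded_by_input_range(self, corridor_grid, two_logger_field):
        p3, v3, w = two_logger_field
        f = mc.interpolate_field(p3, v3, corridor_grid, weights=w)
        assert np.nanmin(f.values) >= 4.0 - 1e-9
        assert np.nanmax(f.values) <= 8.0 + 1e-9

    def test_masked_outside_boundary(self, corridor_grid, two_logger_field):
        p3, v3, w = two_logger_field
        f = mc.interpolate_field(p3, v3, corridor_grid, weights=w)
        assert np.all(np.isnan(f.values[~corridor_grid.inside_mask]))

    def test_insufficient_support(self, corridor_grid):
        with pytest.raises(ValueError, match="insufficient support"):
            mc.sibson_weights(np.array([[1.0, 1.0], [2.0, 1.0]]), corridor_grid)
        collinear = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        with pytest.raises(ValueError, match="insufficient support"):
            mc.sibson_weights(collinear, corridor_grid)


class TestPeriodStack:
    def _fields(self, grid, cell_series):
        out = {}
        for i, v in enumerate(cell_series):
            f = grid.empty_field()
            f[grid.inside_mask] = v
            out[pd.Timestamp(2015, 11, 1) + pd.Timedelta(days=i)] = f
        return out

    def test_cell_statistics_formula(self, corridor_grid):
        fields = self._fields(corridor_grid, [4.0, 6.0, 8.0])
        stack = mc.build_period_stack(fields, mc.NM, corridor_grid)
        m = corridor_grid.inside_mask
        assert stack.layers["Tmin"][m][0] == 4.0
        assert stack.layers["Tmax"][m][0] == 8.0
        assert stack.layers["Tmean"][m][0] == pytest.approx(6.0)
        assert stack.layers["Trange"][m][0] == pytest.approx(4.0)
        assert stack.layers["Tstd"][m][0] == pytest.approx(1.63299, abs=1e-5)

    def test_single_day_degenerate(self, corridor_grid):
        stack = mc.build_period_stack(self._fields(corridor_grid, [5.0]), mc.NM, corridor_grid)
        m = corridor_grid.inside_mask
        assert np.all(stack.layers["Trange"][m] == 0)
        assert np.all(stack.layers["Tstd"][m] == 0)

    def test_trange_identity_and_mask(self, corridor_grid):
        fields = self._fields(corridor_grid, [4.0, 6.0, 8.0])
        stack = mc.build_period_stack(fields, mc.NM, corridor_grid)
        np.testing.assert_allclose(
            stack.layers["Trange"], stack.layers["Tmax"] - stack.layers["Tmin"]
        )
        for arr in stack.layers.values():
            assert np.all(np.isnan(arr[~corridor_grid.inside_mask]))

    def test_empty_period(self, corridor_grid):
        fields = self._fields(corridor_grid, [4.0])
        with pytest.raises(ValueError, match="empty period"):
            mc.build_period_stack(fields, mc.AM, corridor_grid)


class TestValidation:
    def test_mae_rmse_formula(self):
        v = mc.InterpolationValidation("dependent", 1.0, 1.0, np.array([1.0, -1.0]))
        assert v.MAE_C == 1.0
        with pytest.raises(ValueError):
            mc.InterpolationValidation("dependent", 2.0, 1.0, np.array([0.0]))

    def test_residual_examples(self):
        mae, rmse = (
            float(np.mean(np.abs([1, -1]))),
            float(np.sqrt(np.mean(np.square([1, -1])))),
        )
        assert (mae, rmse) == (1.0, 1.0)
        mae2 = float(np.mean(np.abs([0, 2])))
        rmse2 = float(np.sqrt(np.mean(np.square([0, 2]))))
        assert mae2 == 1.0 and rmse2 == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_dependent_perfect_predictions(self, corridor_level):
        # constant field: every leave-one-out prediction equals the truth
        pts = np.array([[15.0, 1.0], [40.0, 1.0], [60.0, 1.0], [85.0, 1.0]])
        vals = np.full(4, 7.7)
        v = mc.dependent_validation(pts, vals, corridor_level)
        assert v.MAE_C == pytest.approx(0.0, abs=1e-9)
        assert v.RMSE_C == pytest.approx(0.0, abs=1e-9)

    def test_dependent_needs_four_loggers(self, corridor_level):
        with pytest.raises(ValueError, match="insufficient loggers"):
            mc.dependent_validation(
                np.array([[10.0, 1.0], [50.0, 1.0], [90.0, 1.0]]),
                np.zeros(3),
                corridor_level,
            )

    def test_independent_validation(self, corridor_grid):
        field = corridor_grid.empty_field()
        field[corridor_grid.inside_mask] = 5.0
        v = mc.independent_validation(
            field, corridor_grid,
            np.array([[10.0, 1.0], [20.0, 1.0]]), np.array([5.0, 7.0]),
        )
        assert v.mode == "independent"
        assert v.MAE_C == pytest.approx(1.0)
        assert v.RMSE_C == pytest.approx(np.sqrt(2), abs=1e-9)
        assert v.MAE_C <= v.RMSE_C


class TestDisturbanceRecovery:
    def test_flat_series(self):
        s = _hourly_series([9.0] * (24 * 10))
        rep = mc.disturbance_recovery(s, "2015-01-08", tolerance_C=0.1)
        assert rep.peak_excess_C == 0.0 and rep.recovery_hours == 0.0

    def test_exponential_decay_crossing_time(self):
        # step +0.4 then exp decay chosen to cross IST + tol at t = 40 h
        tol, peak = 0.1, 0.4
        tau = 40.0 / np.log(peak / tol)
        base = [9.0] * (24 * 8)
        t = np.arange(24 * 10)
        post = 9.0 + peak * np.exp(-t / tau)
        s = _hourly_series(base + list(post))
        t0 = s.timestamps[len(base)]
        rep = mc.disturbance_recovery(s, t0, tolerance_C=tol)
        assert rep.IST_C == pytest.approx(9.0)
        assert rep.peak_excess_C == pytest.approx(peak, abs=1e-6)
        assert rep.recovery_hours == pytest.approx(40.0, abs=1.0)

    def test_monotone_rise_never_recovers(self):
        base = [9.0] * (24 * 8)
        rise = list(9.0 + 0.01 * np.arange(24 * 5))
        s = _hourly_series(base + rise)
        rep = mc.disturbance_recovery(s, s.timestamps[len(base)])
        assert rep.recovery_hours is None

    def test_short_baseline_rejected(self):
        s = _hourly_series([9.0] * 48)
        with pytest.raises(ValueError, match="baseline too short"):
            mc.disturbance_recovery(s, s.timestamps[4])
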