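"""WBGT estimation: indoor regression, outdoor energy balance, 4+4+4 hours."""

import numpy as np
import pytest
import xarray as xr
from scipy.optimize import brentq

from heatlabor.wbgt import (
    DAYLIGHT_LEVELS,
    WBGTInputError,
    WorkdayDef,
    count_threshold_days,
    disaggregate_444,
    globe_temperature,
    hour_levels,
    indoor_wbgt,
    natural_wetbulb,
    outdoor_wbgt,
)


class TestIndoor:
    def test_zero_humidity(self):
        assert indoor_wbgt(30.0, 0.0) == pytest.approx(0.567 * 30 + 3.94, abs=1e-12)

    def test_hand_computed_magnus_case(self):
        # independent arithmetic: e = 0.6 * 6.105 * exp(17.27*30/267.7)
        e = 0.6 * 6.105 * np.exp(17.27 * 30.0 / (237.7 + 30.0))
        assert e == pytest.approx(25.4, abs=0.1)
        assert indoor_wbgt(30.0, 60.0) == pytest.approx(0.567 * 30 + 0.393 * e + 3.94, abs=1e-12)
        assert indoor_wbgt(30.0, 60.0) == pytest.approx(30.9, abs=0.1)

    def test_monotone_in_temperature_and_humidity(self):
        assert indoor_wbgt(31.0, 60.0) > indoor_wbgt(30.0, 60.0)
        assert indoor_wbgt(30.0, 70.0) > indoor_wbgt(30.0, 60.0)

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(WBGTInputError, match="humidity"):
            indoor_wbgt(30.0, 120.0)


# --- independent straight-line oracle for the energy-balance estimator ----
# Scalar re-implementation of the same published-form balances (sphere and
# wetted wick with Lewis-relation mass transfer), solved with brentq instead
# of the pipeline's vectorized bisection.

_SIGMA = 5.670374419e-8
_LEWIS = 0.622 * 2.43e6 / (1005.0 * 1013.25)


def _es(t):
    return 6.105 * np.exp(17.27 * t / (237.7 + t))


def _oracle_globe(ta, rsds, wind):
    h = max(6.3 * wind**0.6, 2.5)
    q = 0.5 * rsds

    def f(tg):
        return q - h * (tg - ta) - 0.95 * _SIGMA * ((tg + 273.15) ** 4 - (ta + 273.15) ** 4)

    return brentq(f, ta - 1.0, ta + q / h + 1.0)


def _oracle_nwb(ta, rh, rsds, wind):
    h = max(8.0 * wind**0.5, 3.0)
    q = 0.15 * rsds
    ea = rh / 100.0 * _es(ta)

    def f(tw):
        return h * (ta - tw) + q - h * _LEWIS * (_es(tw) - ea)

    return brentq(f, ta - 60.0, ta + q / h + 1.0)


def _oracle_wbgt(ta, rh, wind, rsds):
    return 0.7 * _oracle_nwb(ta, rh, rsds, wind) + 0.2 * _oracle_globe(ta, rsds, wind) + 0.1 * ta


ORACLE_POINTS = [
    (25.0, 30.0, 0.5, 100.0),
    (30.0, 50.0, 1.0, 300.0),
    (33.0, 60.0, 2.0, 500.0),
    (37.0, 80.0, 3.0, 700.0),
    (40.0, 40.0, 4.0, 900.0),
]


class TestOutdoor:
    @pytest.mark.parametrize("ta,rh,wind,rsds", ORACLE_POINTS)
    def test_matches_independent_oracle(self, ta, rh, wind, rsds):
        got = outdoor_wbgt(ta, rh, wind, rsds)
        want = _oracle_wbgt(ta, rh, wind, rsds)
        assert got == pytest.approx(want, abs=0.2)

    def test_radiation_monotonicity(self):
        lo = outdoor_wbgt(32.0, 50.0, 1.5, 200.0)
        hi = outdoor_wbgt(32.0, 50.0, 1.5, 800.0)
        assert hi > lo

    def test_wind_cools_when_sunny(self):
        calm = outdoor_wbgt(32.0, 50.0, 0.5, 600.0)
        windy = outdoor_wbgt(32.0, 50.0, 6.0, 600.0)
        assert windy < calm

    def test_high_wind_limit_no_sun(self):
        # with no radiation the globe collapses to air temperature, so the
        # wind dependence of WBGT vanishes as wind grows
        vals = [outdoor_wbgt(33.0, 60.0, u, 0.0) for u in (5.0, 20.0, 80.0)]
        diffs = np.abs(np.diff(vals))
        assert diffs[1] <= diffs[0]
        assert diffs[1] < 0.05

    def test_zero_sun_globe_equals_air(self):
        assert globe_temperature(31.0, 0.0, 2.0) == pytest.approx(31.0, abs=1e-6)

    def test_nwb_below_air_when_unsaturated(self):
        assert natural_wetbulb(35.0, 40.0, 0.0, 2.0) < 35.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(WBGTInputError):
            outdoor_wbgt(30.0, 50.0, -1.0, 100.0)
        with pytest.raises(WBGTInputError):
            outdoor_wbgt(30.0, 50.0, 1.0, -5.0)

    def test_unknown_backend_rejected(self):
        with pytest.raises(WBGTInputError, match="backend"):
            outdoor_wbgt(30.0, 50.0, 1.0, 100.0, backend="nope")

    def test_alternate_backend_monotone(self):
        a = outdoor_wbgt(32.0, 50.0, 1.0, 200.0, backend="swbgt_radiation")
        b = outdoor_wbgt(32.0, 50.0, 1.0, 800.0, backend="swbgt_radiation")
        c = outdoor_wbgt(32.0, 50.0, 5.0, 800.0, backend="swbgt_radiation")
        assert b > a and c < b


class TestDisaggregation444:
    def test_degenerate_day_is_flat(self):
        _, vals = hour_levels(28.0, 28.0)
        assert np.allclose(vals, 28.0)

    def test_levels_arithmetic(self):
        _, vals = hour_levels(28.0, 34.0)
        assert set(np.unique(vals)) <= {28.0, 31.0, 34.0}

    def test_default_workday_multiset_matches_enumeration(self):
        # hand enumeration of the documented layout: worked hours
        # 8,9,10,11,13,14,15,16 -> mean x1 (08), mid x4 (09,10,15,16),
        # max x3 (11,13,14)
        hrs, vals = hour_levels(28.0, 34.0)
        assert hrs == (8, 9, 10, 11, 13, 14, 15, 16)
        expected = sorted([28.0] * 1 + [31.0] * 4 + [34.0] * 3)
        assert sorted(vals.tolist()) == expected

    def test_delay_shifts_window(self):
        wd2 = WorkdayDef(delay_h=2)
        hrs, vals = hour_levels(28.0, 34.0, wd2)
        assert hrs == (10, 11, 12, 13, 15, 16, 17, 18)
        # two late hours fall back to the daily mean
        assert sorted(vals.tolist()) == sorted([28.0] * 2 + [31.0] * 3 + [34.0] * 3)

    def test_work_hours_bounded_by_daily_range(self):
        rng = np.random.default_rng(7)
        mean = rng.uniform(20, 32, 50)
        mx = mean + rng.uniform(0, 8, 50)
        for wd in (WorkdayDef(), WorkdayDef(delay_h=1), WorkdayDef(delay_h=2)):
            _, vals = hour_levels(mean, mx, wd)
            assert vals.shape == (8, 50)
            assert np.all(vals >= mean[None, :] - 1e-12)
            assert np.all(vals <= mx[None, :] + 1e-12)

    def test_invalid_workday_rejected(self):
        with pytest.raises(WBGTInputError, match="8 worked hours"):
            WorkdayDef(start=8, lunch_start=12, lunch_end=13, end=18).hours()

    def test_max_below_mean_rejected(self):
        with pytest.raises(WBGTInputError, match="max WBGT"):
            hour_levels(30.0, 28.0)

    def test_xarray_wrapper_dims(self):
        da = xr.DataArray(np.full((4, 2), 28.0), dims=("time", "x"))
        db = xr.DataArray(np.full((4, 2), 34.0), dims=("time", "x"))
        out = disaggregate_444(da, db)
        assert out.dims == ("work_hour", "time", "x")
        assert out.sizes["work_hour"] == 8


def _daily_ds(values, years):
    nyears = len(years)
    t = np.arange(nyears * 365)
    return xr.Dataset(
        {"wbgt_mean_indoor": (("time",), values)},
        coords={"time": t, "year": ("time", np.repeat(years, 365))},
    )


class TestThresholdDays:
    def test_always_above(self):
        ds = _daily_ds(np.full(365, 30.0), [2000])
        assert float(count_threshold_days(ds, 25.0, (2000, 2000))) == 365

    def test_never_above(self):
        ds = _daily_ds(np.full(365, 20.0), [2000])
        assert float(count_threshold_days(ds, 25.0, (2000, 2000))) == 0

    def test_sinusoid_crossing_window(self):
        # wbgt(d) = 25 + 5*cos(2*pi*(d - 182)/365) crosses 25 where the
        # cosine is non-negative: exactly the days with |d-182| <= 91.25,
        # i.e. days 91..273 inclusive -> 183 days
        d = np.arange(365)
        vals = 25.0 + 5.0 * np.cos(2 * np.pi * (d - 182) / 365)
        expected = int(np.sum(np.cos(2 * np.pi * (d - 182) / 365) >= 0))
        ds = _daily_ds(vals, [2000])
        assert float(count_threshold_days(ds, 25.0, (2000, 2000))) == expected == 183

    def test_period_outside_data_rejected(self):
        ds = _daily_ds(np.full(365, 30.0), [2000])
        with pytest.raises(WBGTInputError):
            count_threshold_days(ds, 25.0, (2010, 2020))
        with pytest.raises(WBGTInputError, match="empty"):
            count_threshold_days(ds, 25.0, (2001, 2000))
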