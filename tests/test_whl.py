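"""WHL computation and aggregation: per-capita, totals, provinces, jobs."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.stats import norm

from heatlabor.erf import ERFParams
from heatlabor.exposure import SECTORS
from heatlabor.wbgt import WorkdayDef
from heatlabor.whl import (
    PeriodDef,
    WHLError,
    aggregate,
    fulltime_job_equivalents,
    fulltime_jobs_millions,
    per_capita_whl_annual,
    per_capita_whl_daily,
    total_whl,
)


def flat_params(m=33.0, s=4.0):
    return ERFParams(prodmean={200: m, 300: m, 400: m},
                     prodsd={200: s, 300: s, 400: s})


def wbgt_ds(mean, mx, ndays=1, years=None, shape=(1, 1)):
    ny, nx = shape
    if years is None:
        years = [2000]
    t = np.arange(len(years) * ndays)
    year_of = np.repeat(years, ndays)
    data = {
        name: (("time", "y", "x"), np.full((t.size, ny, nx), val))
        for name, val in (
            ("wbgt_mean_indoor", mean), ("wbgt_max_indoor", mx),
            ("wbgt_mean_outdoor", mean), ("wbgt_max_outdoor", mx),
        )
    }
    return xr.Dataset(data, coords={"time": t, "year": ("time", year_of)})


class TestPerCapita:
    def test_half_loss_every_hour_gives_4h(self):
        # all work-hour WBGT at the curve location: 8 hours x 0.5 loss
        ds = wbgt_ds(33.0, 33.0)
        daily = per_capita_whl_daily(ds, "manufacturing", flat_params())
        assert float(daily.isel(time=0, y=0, x=0)) == pytest.approx(4.0, abs=1e-12)

    def test_cool_day_loses_nothing(self):
        ds = wbgt_ds(33.0 - 40.0, 33.0 - 40.0)
        daily = per_capita_whl_daily(ds, "service", flat_params())
        assert float(daily.isel(time=0, y=0, x=0)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_level_sum(self):
        # mean 28 / max 34 -> levels (28, 31, 34); default workday hour
        # multiset is 1 x mean, 4 x mid, 3 x max; m=33, s=4
        ds = wbgt_ds(28.0, 34.0)
        daily = per_capita_whl_daily(ds, "manufacturing", flat_params())
        expected = (
            1 * norm.cdf((28 - 33) / 4)
            + 4 * norm.cdf((31 - 33) / 4)
            + 3 * norm.cdf((34 - 33) / 4)
        )
        assert float(daily.isel(time=0, y=0, x=0)) == pytest.approx(expected, abs=1e-9)

    def test_annual_sums_days(self):
        ds = wbgt_ds(33.0, 33.0, ndays=100, years=[2000])
        annual = per_capita_whl_annual(ds, "manufacturing", flat_params())
        assert float(annual.sel(year=2000).isel(y=0, x=0)) == pytest.approx(400.0)

    def test_monotone_under_uniform_warming(self):
        rng = np.random.default_rng(1)
        mean = rng.uniform(22, 32, (10, 2, 2))
        span = rng.uniform(0, 6, (10, 2, 2))
        base = wbgt_ds(0.0, 0.0, ndays=10, shape=(2, 2))
        warm = base.copy(deep=True)
        for v in base.data_vars:
            is_max = "max" in v
            base[v].values[:] = mean + (span if is_max else 0.0)
            warm[v].values[:] = mean + 1.0 + (span if is_max else 0.0)
        p = flat_params()
        for sector in SECTORS:
            d0 = per_capita_whl_daily(base, sector, p)
            d1 = per_capita_whl_daily(warm, sector, p)
            assert np.all(d1.values >= d0.values)

    def test_unknown_sector_rejected(self):
        with pytest.raises(WHLError, match="sector"):
            per_capita_whl_daily(wbgt_ds(30, 32), "mining", flat_params())

    def test_heavier_outdoor_work_loses_more(self, truth_params):
        # same cell-day: 400 W outdoor loss >= 200 W indoor loss when the
        # outdoor WBGT is at least the indoor one
        ds = wbgt_ds(30.0, 34.0)
        agri = per_capita_whl_daily(ds, "agriculture", truth_params)
        svc = per_capita_whl_daily(ds, "service", truth_params)
        assert float(agri.isel(time=0, y=0, x=0)) >= float(svc.isel(time=0, y=0, x=0))


class TestTotal:
    def test_single_cell_product(self):
        ds = wbgt_ds(33.0, 33.0, ndays=100)
        p = flat_params()
        pc = {s: per_capita_whl_annual(ds, s, p) for s in SECTORS}
        exposed = xr.Dataset(
            {s: (("year", "y", "x"), np.array([[[1000.0 if s == "manufacturing" else 0.0]]]))
             for s in SECTORS},
            coords={"year": [2000]},
        )
        whl = total_whl(pc, exposed)
        # 4 h/day x 100 days x 1000 workers
        assert whl["total"].sel(year=2000).values.item() == pytest.approx(400_000.0)

    def test_zero_population_zero_whl(self):
        ds = wbgt_ds(35.0, 38.0, ndays=10)
        p = flat_params()
        pc = {s: per_capita_whl_annual(ds, s, p) for s in SECTORS}
        exposed = xr.Dataset(
            {s: (("year", "y", "x"), np.zeros((1, 1, 1))) for s in SECTORS},
            coords={"year": [2000]},
        )
        whl = total_whl(pc, exposed)
        assert float(whl["total"].sum()) == 0.0

    def test_brute_force_multicell(self):
        rng = np.random.default_rng(9)
        ds = wbgt_ds(30.0, 34.0, ndays=5, shape=(2, 2))
        for v in ds.data_vars:
            ds[v].values += rng.uniform(-2, 2, ds[v].shape)
        ds["wbgt_max_indoor"] = ds["wbgt_mean_indoor"] + 3.0
        ds["wbgt_max_outdoor"] = ds["wbgt_mean_outdoor"] + 3.0
        p = flat_params()
        pops = {s: rng.uniform(0, 500, (1, 2, 2)) for s in SECTORS}
        exposed = xr.Dataset(
            {s: (("year", "y", "x"), pops[s]) for s in SECTORS},
            coords={"year": [2000]},
        )
        pc = {s: per_capita_whl_annual(ds, s, p) for s in SECTORS}
        whl = total_whl(pc, exposed)
        # loop recomputation
        expected = np.zeros((2, 2))
        for s in SECTORS:
            pc_s = pc[s].sel(year=2000).values
            expected += pc_s * pops[s][0]
        np.testing.assert_allclose(whl["total"].sel(year=2000).values, expected, rtol=1e-12)


class TestAggregate:
    def _whl(self, shape=(4, 4), years=(2000, 2001), ngcm=2, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 1000, (ngcm, len(years), *shape))
        total = xr.DataArray(
            data, dims=("gcm", "year", "y", "x"),
            coords={"gcm": [f"pgcm{i}" for i in range(ngcm)], "year": list(years)},
        )
        return xr.Dataset({"total": total})

    def test_single_province_equals_national(self):
        whl = self._whl()
        labels = np.zeros((4, 4), dtype=int)
        df = aggregate(whl, labels, ["ALL"], periods=(PeriodDef("p", 2000, 2001),))
        by = df.set_index("province")
        assert by.loc["ALL", "whl_mean"] == pytest.approx(by.loc["NATIONAL", "whl_mean"])
        assert by.loc["ALL", "proportion"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        whl = self._whl()
        labels = np.repeat(np.arange(4), 4).reshape(4, 4)
        df = aggregate(whl, labels, ["A", "B", "C", "D"],
                       periods=(PeriodDef("p", 2000, 2001),))
        provs = df[df.province != "NATIONAL"]
        assert provs["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_province_mask_oracle(self):
        whl = self._whl(shape=(2, 2), ngcm=1)
        labels = np.array([[0, 0], [1, 1]])
        df = aggregate(whl, labels, ["N", "S"], periods=(PeriodDef("p", 2000, 2001),))
        manual_n = float(whl["total"].isel(gcm=0, y=slice(0, 1)).mean("year").sum())
        got = df.set_index("province").loc["N", "whl_mean"]
        assert got == pytest.approx(manual_n, rel=1e-12)

    def test_interval_contains_mean_and_modes(self):
        whl = self._whl(ngcm=3)
        labels = np.zeros((4, 4), dtype=int)
        for mode in ("minmax", "normal"):
            df = aggregate(whl, labels, ["ALL"], periods=(PeriodDef("p", 2000, 2001),),
                           interval=mode)
            assert np.all(df["whl_lo"] <= df["whl_mean"] + 1e-9)
            assert np.all(df["whl_hi"] >= df["whl_mean"] - 1e-9)

    def test_period_outside_rejected(self):
        whl = self._whl()
        labels = np.zeros((4, 4), dtype=int)
        with pytest.raises(WHLError, match="outside"):
            aggregate(whl, labels, ["ALL"], periods=(PeriodDef("x", 2050, 2060),))


class TestJobEquivalents:
    @pytest.mark.parametrize(
        "hours,millions",
        [(32.1e9, 11), (8.5e9, 3), (0.0, 0)],
    )
    def test_printed_conversions(self, hours, millions):
        # 8 h/day x 365 d = 2920 h per full-time job-year
        assert fulltime_jobs_millions(hours) == millions

    def test_exact_division(self):
        assert fulltime_job_equivalents(2920.0) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(WHLError):
            fulltime_job_equivalents(-1.0)
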