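"""Work hours lost (WHL): per-capita and population-total heat-induced losses.

A worker's daily loss is the sum over the 8 worked clock hours of the loss
fraction evaluated at that hour's WBGT.  Under the "4 + 4 + 4" hourly
disaggregation each worked hour sits at one of three levels (daily mean,
max-mean midpoint, daily max), so the daily per-capita loss reduces to

    whl_day = n_mean * L(w_mean) + n_mid * L(w_mid) + n_max * L(w_max)

with the level counts fixed by the workday definition.  Total WHL multiplies
per-capita losses by the exposed working population per sector, then
aggregates over cells to provinces and the nation, periods, and the
pseudo-GCM ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .erf import ERFParams, SECTOR_INTENSITY, SECTOR_SETTING, loss_fraction
from .exposure import SECTORS
from .wbgt import DEFAULT_WORKDAY, WorkdayDef

HOURS_PER_WORKDAY = 8
DAYS_PER_WORKYEAR = 365  # every calendar day a potential workday
HOURS_PER_FULLTIME_JOB_YEAR = HOURS_PER_WORKDAY * DAYS_PER_WORKYEAR  # 2920


class WHLError(ValueError):
    """Raised for inconsistent WHL inputs."""


@dataclass(frozen=True)
class PeriodDef:
    """A labelled inclusive year range, e.g. the 2081-2100 'late' period."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise WHLError(f"period {self.label}: start must not exceed end")

    def mask(self, years) -> np.ndarray:
        y = np.asarray(years)
        return (y >= self.start_year) & (y <= self.end_year)


#: the study periods: a 1986-2005 baseline and three 20-year future windows
STANDARD_PERIODS = (
    PeriodDef("baseline", 1986, 2005),
    PeriodDef("early", 2021, 2040),
    PeriodDef("middle", 2051, 2070),
    PeriodDef("late", 2081, 2100),
)


def per_capita_whl_daily(
    wbgt_daily: xr.Dataset,
    sector: str,
    erf: ERFParams,
    workday: WorkdayDef = DEFAULT_WORKDAY,
) -> xr.DataArray:
    """Hours lost per worker per day for one sector (dims of the daily WBGT).

    Picks the sector's indoor/outdoor WBGT fields and work intensity, forms
    the three 4+4+4 levels and sums the loss fraction over the worked hours
    via the workday's level counts.
    """
    if sector not in SECTORS:
        raise WHLError(f"unknown sector {sector!r}")
    setting = SECTOR_SETTING[sector]
    intensity = SECTOR_INTENSITY[sector]
    wmean = wbgt_daily[f"wbgt_mean_{setting}"]
    wmax = wbgt_daily[f"wbgt_max_{setting}"]
    levels = {"mean": wmean, "mid": 0.5 * (wmean + wmax), "max": wmax}
    counts = workday.level_counts()
    out = sum(
        n * xr.apply_ufunc(loss_fraction, levels[lv], kwargs={"intensity": intensity, "params": erf})
        for lv, n in counts.items()
    )
    out.attrs["units"] = "h worker-1 day-1"
    out.attrs["sector"] = sector
    return out


def per_capita_whl_annual(
    wbgt_daily: xr.Dataset,
    sector: str,
    erf: ERFParams,
    workday: WorkdayDef = DEFAULT_WORKDAY,
) -> xr.DataArray:
    """Annual per-capita WHL (h/worker/year): daily losses summed by year."""
    daily = per_capita_whl_daily(wbgt_daily, sector, erf, workday)
    annual = daily.groupby(wbgt_daily["year"]).sum("time")
    annual.attrs["units"] = "h worker-1 year-1"
    annual.attrs["sector"] = sector
    return annual


def total_whl(per_capita_annual: dict[str, xr.DataArray],
              exposed: xr.Dataset) -> xr.Dataset:
    """Population-total WHL per sector: per-capita x exposed workers.

    ``per_capita_annual`` maps sector -> annual per-capita WHL with a
    ``year`` dimension; ``exposed`` is the AC-adjusted population.  Years
    present in both are used.  Adds ``total`` = sum over sectors.
    """
    out = {}
    for sector, pc in per_capita_annual.items():
        if sector not in SECTORS:
            raise WHLError(f"unknown sector {sector!r}")
        if np.any(pc.values < 0) or np.any(exposed[sector].values < 0):
            raise WHLError("negative per-capita WHL or population")
        out[sector] = pc * exposed[sector]
    ds = xr.Dataset(out)
    ds["total"] = sum(ds[s] for s in out)
    ds.attrs["units"] = "h year-1"
    return ds


def aggregate(
    whl: xr.Dataset,
    province_labels: np.ndarray,
    province_names: list[str],
    periods=STANDARD_PERIODS,
    interval: str = "minmax",
) -> pd.DataFrame:
    """Province/period summary of total WHL with ensemble intervals.

    Returns a tidy frame with columns (province, period, whl_mean, whl_lo,
    whl_hi, proportion): annual-mean national-plus-province totals per
    period, ensemble mean and 95% interval across pseudo-GCMs (``minmax``
    default — with few ensemble members the interval is the ensemble
    min/max; ``normal`` gives mean +/- 1.96 sd), and each province's share
    of the national total.
    """
    if interval not in ("minmax", "normal"):
        raise WHLError(f"unknown interval mode {interval!r}")
    labels = np.asarray(province_labels)
    total = whl["total"]
    years = total["year"].values
    rows = []
    for period in periods:
        m = period.mask(years)
        if not m.any():
            raise WHLError(f"period {period.label} outside the data years")
        annual = total.isel(year=m).mean("year")  # (gcm, y, x)
        prov_by_gcm = {}
        for k, name in enumerate(province_names):
            mask = xr.DataArray(labels == k, dims=("y", "x"))
            prov_by_gcm[name] = annual.where(mask, 0.0).sum(("y", "x"))
        nat = sum(prov_by_gcm.values())
        nat_mean = float(nat.mean("gcm"))
        for name, vals in prov_by_gcm.items():
            mean = float(vals.mean("gcm"))
            lo, hi = _interval(vals, interval)
            rows.append(
                {
                    "province": name,
                    "period": period.label,
                    "whl_mean": mean,
                    "whl_lo": lo,
                    "whl_hi": hi,
                    "proportion": mean / nat_mean if nat_mean else np.nan,
                }
            )
        lo, hi = _interval(nat, interval)
        rows.append(
            {
                "province": "NATIONAL",
                "period": period.label,
                "whl_mean": nat_mean,
                "whl_lo": lo,
                "whl_hi": hi,
                "proportion": 1.0 if nat_mean else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _interval(vals: xr.DataArray, mode: str) -> tuple[float, float]:
    if mode == "minmax" or vals.sizes.get("gcm", 1) < 3:
        return float(vals.min("gcm")), float(vals.max("gcm"))
    sd = float(vals.std("gcm", ddof=1))
    mean = float(vals.mean("gcm"))
    return mean - 1.96 * sd, mean + 1.96 * sd


def national_series(whl: xr.Dataset) -> xr.DataArray:
    """National annual total WHL (gcm, year)."""
    return whl["total"].sum(("y", "x"))


def fulltime_job_equivalents(whl_hours) -> float:
    """Annual WHL expressed as equivalent full-time jobs (8 h/day x 365 d)."""
    whl_hours = np.asarray(whl_hours, dtype=float)
    if np.any(whl_hours < 0):
        raise WHLError("WHL hours must be >= 0")
    out = whl_hours / HOURS_PER_FULLTIME_JOB_YEAR
    return out if out.ndim else float(out)


def fulltime_jobs_millions(whl_hours) -> int:
    """Job equivalents rounded to the nearest million, for display."""
    return int(round(fulltime_job_equivalents(whl_hours) / 1e6))
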