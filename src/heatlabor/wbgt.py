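"""Wet-bulb globe temperature (WBGT) from daily gridded meteorology.

Indoor WBGT uses the simplified two-variable regression (sWBGT) on air
temperature and water-vapor pressure.  Outdoor WBGT uses the standard
composition

    WBGT = 0.7 * Tnwb + 0.2 * Tg + 0.1 * Ta

with the natural wet-bulb temperature ``Tnwb`` and globe temperature ``Tg``
obtained from a Liljegren-style iterative energy-balance estimator (the
default backend) that includes wind speed and shortwave radiation; a simple
radiation-adjusted sWBGT regression is available as an alternate backend.

Daily mean/max WBGT is disaggregated to clock-hour values with the
"4 + 4 + 4" method: within a 12-h daylight block, 4 h sit at the daily max,
4 h at the max-mean midpoint and 4 h at the daily mean; hours outside the
block carry the daily mean.  A workday definition selects which 8 clock
hours are worked (default 08:00-12:00 and 13:00-17:00, optionally delayed
by 1-2 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import xarray as xr

STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
_LEWIS = 0.622 * 2.43e6 / (1005.0 * 1013.25)  # W m-2 per (W m-2 K-1) per hPa

# energy-balance backend constants (see docs/methods.md)
_GLOBE_EMISSIVITY = 0.95
_GLOBE_SOLAR_FRACTION = 0.5   # absorbed solar per unit convective area
_GLOBE_H_COEF = 6.3           # h = max(coef * u**0.6, floor), sphere
_GLOBE_H_FLOOR = 2.5          # free-convection floor, W m-2 K-1
_WICK_SOLAR_FRACTION = 0.15   # wick albedo 0.4, cylindrical geometry
_WICK_H_COEF = 8.0            # h = max(coef * u**0.5, floor), cylinder
_WICK_H_FLOOR = 3.0

#: wind speed assumed at indoor workplaces (m/s) where a wind term is needed
INDOOR_WIND_MS = 1.0


class WBGTInputError(ValueError):
    """Raised for physically invalid meteorological inputs."""


def saturation_vapor_pressure(ta):
    """Saturation vapor pressure (hPa) at air temperature ta (deg C), Magnus form."""
    ta = np.asarray(ta, dtype=float)
    return 6.105 * np.exp(17.27 * ta / (237.7 + ta))


def vapor_pressure(ta, rh):
    """Actual vapor pressure (hPa) from temperature (deg C) and RH (%)."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise WBGTInputError("relative humidity must lie in [0, 100] %")
    return (rh / 100.0) * saturation_vapor_pressure(ta)


def indoor_wbgt(ta, rh):
    """Simplified (indoor) WBGT in deg C: 0.567*Ta + 0.393*e + 3.94.

    ``e`` is the vapor pressure in hPa from the Magnus saturation formula.
    Elementwise; accepts scalars or arrays.
    """
    e = vapor_pressure(ta, rh)
    out = 0.567 * np.asarray(ta, dtype=float) + 0.393 * e + 3.94
    return out if out.ndim else float(out)


def _bisect(f, lo, hi, iterations=48):
    """Vectorized bisection for a decreasing-in-x residual f."""
    lo = np.array(np.broadcast_to(lo, np.shape(f(lo))), dtype=float, copy=True)
    hi = np.array(np.broadcast_to(hi, lo.shape), dtype=float, copy=True)
    flo = f(lo)
    fhi = f(hi)
    bad = (flo < 0) | (fhi > 0)
    if np.any(bad):
        raise WBGTInputError(
            f"energy-balance solver failed to bracket a root in {int(bad.sum())} cell(s)"
        )
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_lo = fm > 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def globe_temperature(ta, rsds, wind):
    """Globe temperature (deg C) from an energy balance on a black globe.

    Absorbed shortwave is balanced against convection to air and longwave
    exchange with surroundings at air temperature:

        h(u) * (Tg - Ta) + eps*sigma*(Tg^4 - Ta^4) = f_sol * S

    Tg -> Ta as wind grows or as S -> 0.
    """
    ta = np.asarray(ta, dtype=float)
    rsds = np.asarray(rsds, dtype=float)
    wind = np.asarray(wind, dtype=float)
    h = np.maximum(_GLOBE_H_COEF * np.maximum(wind, 0.0) ** 0.6, _GLOBE_H_FLOOR)
    q = _GLOBE_SOLAR_FRACTION * rsds
    ta_k = ta + 273.15

    def resid(tg):
        return q - h * (tg - ta) - _GLOBE_EMISSIVITY * STEFAN_BOLTZMANN * (
            (tg + 273.15) ** 4 - ta_k**4
        )

    # q/h bounds the convective excess, so [ta - 0.5, ta + q/h + 0.1]
    # always brackets the root (radiative exchange only tightens it)
    return _bisect(resid, ta - 0.5, ta + q / h + 0.1)


def natural_wetbulb(ta, rh, rsds, wind):
    """Natural wet-bulb temperature (deg C) from a wetted-wick energy balance.

    Evaporative cooling balances convective and absorbed-solar heating, with
    the mass-transfer coefficient tied to the convective one by the Lewis
    relation:

        h(u)*L_rel*(es(Tnwb) - ea) = h(u)*(Ta - Tnwb) + f_sol * S

    With S = 0 this reduces to the psychrometric wet bulb; radiation raises
    Tnwb and wind pulls it back toward the psychrometric limit.
    """
    ta = np.asarray(ta, dtype=float)
    rsds = np.asarray(rsds, dtype=float)
    wind = np.asarray(wind, dtype=float)
    ea = vapor_pressure(ta, rh)
    h = np.maximum(_WICK_H_COEF * np.maximum(wind, 0.0) ** 0.5, _WICK_H_FLOOR)
    q = _WICK_SOLAR_FRACTION * rsds

    def resid(tw):
        return h * (ta - tw) + q - h * _LEWIS * (saturation_vapor_pressure(tw) - ea)

    # upper bound ta + q/h + 0.1: es(T) >= ea there (rh <= 100), so resid < 0;
    # lower bound ta - 60 is below any physical wet-bulb depression
    return _bisect(resid, ta - 60.0, ta + q / h + 0.1)


def outdoor_wbgt(ta, rh, wind, rsds, backend="energy_balance"):
    """Outdoor WBGT (deg C): 0.7*Tnwb + 0.2*Tg + 0.1*Ta.

    ``backend="energy_balance"`` (default) solves the globe and natural
    wet-bulb energy balances; ``backend="swbgt_radiation"`` is a cheap
    regression alternative adding a wind-damped radiation term to sWBGT.
    Non-decreasing in rsds; non-increasing in wind when rsds > 0.
    """
    wind_a = np.asarray(wind, dtype=float)
    rsds_a = np.asarray(rsds, dtype=float)
    if np.any(wind_a < 0):
        raise WBGTInputError("wind speed must be >= 0")
    if np.any(rsds_a < 0):
        raise WBGTInputError("shortwave radiation must be >= 0")
    if backend == "energy_balance":
        tnwb = natural_wetbulb(ta, rh, rsds, wind)
        tg = globe_temperature(ta, rsds, wind)
        out = 0.7 * tnwb + 0.2 * tg + 0.1 * np.asarray(ta, dtype=float)
    elif backend == "swbgt_radiation":
        out = indoor_wbgt(ta, rh) + 0.002 * rsds_a / (1.0 + 0.5 * np.maximum(wind_a, 0.0))
        out = np.asarray(out, dtype=float)
    else:
        raise WBGTInputError(f"unknown outdoor WBGT backend {backend!r}")
    return out if out.ndim else float(out)


def compute_wbgt_daily(climate: xr.Dataset, backend: str = "energy_balance",
                       rsds_peak_factor: float = 2.0) -> xr.Dataset:
    """Daily mean and max indoor/outdoor WBGT from a daily climate dataset.

    Expects variables ``tas``, ``tasmax``, ``hurs``, ``sfcWind``, ``rsds``.
    Mean WBGT pairs the daily-mean temperature with the daily-mean radiation;
    max WBGT pairs the daily-max temperature with radiation scaled by
    ``rsds_peak_factor`` (midday peak of the diurnal insolation cycle).
    Humidity and wind are daily values used for both.
    """
    tas = climate["tas"]
    tasmax = climate["tasmax"]
    hurs = climate["hurs"]
    wind = climate["sfcWind"]
    rsds = climate["rsds"]
    ind_mean = xr.apply_ufunc(indoor_wbgt, tas, hurs)
    ind_max = xr.apply_ufunc(indoor_wbgt, tasmax, hurs)
    out_mean = xr.apply_ufunc(
        outdoor_wbgt, tas, hurs, wind, rsds, kwargs={"backend": backend}
    )
    out_max = xr.apply_ufunc(
        outdoor_wbgt, tasmax, hurs, wind, rsds * rsds_peak_factor,
        kwargs={"backend": backend},
    )
    ds = xr.Dataset(
        {
            "wbgt_mean_indoor": ind_mean,
            "wbgt_max_indoor": ind_max,
            "wbgt_mean_outdoor": out_mean,
            "wbgt_max_outdoor": out_max,
        },
        attrs=dict(climate.attrs),
    )
    for v in ds.data_vars.values():
        v.attrs["units"] = "degC"
    return ds


# ---------------------------------------------------------------------------
# "4 + 4 + 4" hourly disaggregation

#: clock hours (start of hour) of the 12-h daylight block and their level:
#: 11:00-15:00 at daily max, 09:00-11:00 + 15:00-17:00 at the midpoint,
#: 07:00-09:00 + 17:00-19:00 at the daily mean.  Hours outside the block
#: carry the daily mean.
DAYLIGHT_LEVELS = {
    7: "mean", 8: "mean", 17: "mean", 18: "mean",
    9: "mid", 10: "mid", 15: "mid", 16: "mid",
    11: "max", 12: "max", 13: "max", 14: "max",
}


@dataclass(frozen=True)
class WorkdayDef:
    """An 8-hour workday: morning + afternoon spans, optionally delayed.

    ``start`` is the first worked clock hour; ``lunch_start``/``lunch_end``
    bound a break; the afternoon runs to ``end``.  ``delay_h`` shifts the
    whole window later (0, 1 or 2 h in the delayed-evening analyses).
    """

    start: int = 8
    lunch_start: int = 12
    lunch_end: int = 13
    end: int = 17
    delay_h: int = 0

    def hours(self) -> tuple[int, ...]:
        s, ls, le, e = (
            self.start + self.delay_h,
            self.lunch_start + self.delay_h,
            self.lunch_end + self.delay_h,
            self.end + self.delay_h,
        )
        hrs = tuple(range(s, ls)) + tuple(range(le, e))
        if len(hrs) != 8:
            raise WBGTInputError(
                f"workday must total 8 worked hours, got {len(hrs)}: {hrs}"
            )
        if hrs[-1] >= 24:
            raise WBGTInputError("workday extends past midnight")
        return hrs

    def level_counts(self) -> Counter:
        """How many worked hours sit at each 4+4+4 level."""
        return Counter(DAYLIGHT_LEVELS.get(h, "mean") for h in self.hours())


DEFAULT_WORKDAY = WorkdayDef()


def hour_levels(wbgt_mean, wbgt_max, workday: WorkdayDef = DEFAULT_WORKDAY):
    """Per-work-hour WBGT values as an array stacked on a new leading axis.

    Returns (hours, values) where ``values[k]`` is the WBGT during worked
    clock hour ``hours[k]``, broadcast over the input shape.
    """
    wbgt_mean = np.asarray(wbgt_mean, dtype=float)
    wbgt_max = np.asarray(wbgt_max, dtype=float)
    if np.any(wbgt_max < wbgt_mean):
        raise WBGTInputError("daily max WBGT must be >= daily mean WBGT")
    levels = {
        "mean": wbgt_mean,
        "mid": 0.5 * (wbgt_mean + wbgt_max),
        "max": wbgt_max,
    }
    hrs = workday.hours()
    vals = np.stack([levels[DAYLIGHT_LEVELS.get(h, "mean")] for h in hrs], axis=0)
    return hrs, vals


def disaggregate_444(wbgt_mean: xr.DataArray, wbgt_max: xr.DataArray,
                     workday: WorkdayDef = DEFAULT_WORKDAY) -> xr.DataArray:
    """Work-hour WBGT as an xarray with a leading ``work_hour`` dimension."""
    hrs, vals = hour_levels(wbgt_mean.values, wbgt_max.values, workday)
    return xr.DataArray(
        vals,
        dims=("work_hour",) + tuple(wbgt_mean.dims),
        coords={"work_hour": list(hrs), **dict(wbgt_mean.coords)},
        attrs={"units": "degC", "workday": repr(workday)},
    )


def count_threshold_days(wbgt_daily: xr.Dataset, threshold: float,
                         years: tuple[int, int], var: str = "wbgt_mean_indoor") -> xr.DataArray:
    """Per-cell annual mean number of days with WBGT >= threshold.

    ``years`` is an inclusive (start, end) calendar-year window; the dataset
    must carry a ``year`` coordinate along ``time``.
    """
    y0, y1 = years
    if y1 < y0:
        raise WBGTInputError(f"empty period {years}")
    yr = wbgt_daily["year"]
    sel = wbgt_daily[var].where((yr >= y0) & (yr <= y1), drop=True)
    if sel.sizes.get("time", 0) == 0:
        raise WBGTInputError(f"period {years} outside the data's time range")
    exceed = (sel >= threshold).groupby(sel["year"]).sum("time")
    return exceed.mean("year")
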