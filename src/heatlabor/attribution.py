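"""Driver attribution and 1.5 degC avoided-loss benefits.

Factor separation evaluates the WHL at the four combinations of
(climate, population) states:

    total       = W(C1, P1) - W(C0, P0)
    climate     = W(C1, P0) - W(C0, P0)
    population  = W(C0, P1) - W(C0, P0)
    interaction = total - climate - population

so the three driver terms add to the total change exactly.  The 1.5 degC
benefit uses mid-century (2051-2070) WBGT under a stabilized low-warming
scenario in place of each RCP, holding population at its mid-century
average: avoided WHL = (per-capita loss under RCP - per-capita loss at
1.5 degC) x average exposed population.  Its economic value follows the
human-capital method: avoided hours times the unit value of a work hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .erf import ERFParams
from .exposure import SECTORS
from .wbgt import DEFAULT_WORKDAY, WorkdayDef
from .whl import PeriodDef, per_capita_whl_annual


class AttributionError(ValueError):
    """Raised for inconsistent attribution inputs."""


@dataclass(frozen=True)
class DriverDecomposition:
    """Change in WHL split into climate, population and interaction terms."""

    total_change: float
    climate_effect: float
    population_effect: float
    interaction_effect: float

    def as_dict(self) -> dict:
        return {
            "total_change": self.total_change,
            "climate_effect": self.climate_effect,
            "population_effect": self.population_effect,
            "interaction_effect": self.interaction_effect,
        }


def factor_separation(whl_fn, climate0, climate1, pop0, pop1) -> DriverDecomposition:
    """Decompose W(C1,P1) - W(C0,P0) into driver contributions.

    ``whl_fn(climate, pop)`` evaluates the outcome at any corner; the
    interaction is the residual after removing the single-factor effects,
    so the decomposition is additive to machine precision by construction.
    """
    try:
        w00 = whl_fn(climate0, pop0)
        w10 = whl_fn(climate1, pop0)
        w01 = whl_fn(climate0, pop1)
        w11 = whl_fn(climate1, pop1)
    except Exception as exc:  # noqa: BLE001 - corner failure is a caller error
        raise AttributionError(f"WHL evaluator failed at a corner: {exc}") from exc
    total = w11 - w00
    climate = w10 - w00
    population = w01 - w00
    return DriverDecomposition(
        total_change=total,
        climate_effect=climate,
        population_effect=population,
        interaction_effect=total - climate - population,
    )


MID_CENTURY = PeriodDef("middle", 2051, 2070)


def avoided_whl_15c(
    wbgt_15: xr.Dataset,
    wbgt_rcp: xr.Dataset,
    exposed_mid: xr.Dataset,
    erf: ERFParams,
    workday: WorkdayDef = DEFAULT_WORKDAY,
    period: PeriodDef = MID_CENTURY,
    truncate_negative: bool = False,
) -> xr.Dataset:
    """Avoided WHL from meeting the 1.5 degC goal, per sector and cell.

    Both WBGT datasets must cover ``period``; ``exposed_mid`` is the
    period-average exposed population (dims y, x per sector).  Cells where
    the RCP is cooler than the 1.5 degC set yield negative avoided losses;
    they are kept (and counted in the ``n_negative_cells`` attribute) unless
    ``truncate_negative`` is set.
    """
    out = {}
    n_neg = 0
    for sector in SECTORS:
        pc15 = _period_mean_pc(wbgt_15, sector, erf, workday, period)
        pcr = _period_mean_pc(wbgt_rcp, sector, erf, workday, period)
        diff = pcr - pc15
        avoided = diff * exposed_mid[sector]
        n_neg += int((avoided.values < 0).sum())
        if truncate_negative:
            avoided = avoided.clip(min=0.0)
        out[sector] = avoided
    ds = xr.Dataset(out)
    ds["total"] = sum(ds[s] for s in SECTORS)
    ds.attrs["units"] = "h year-1"
    ds.attrs["n_negative_cells"] = n_neg
    ds.attrs["period"] = f"{period.start_year}-{period.end_year}"
    return ds


def _period_mean_pc(wbgt_ds, sector, erf, workday, period):
    years = wbgt_ds["year"].values
    if not period.mask(np.unique(years)).all() or np.unique(years).size == 0:
        uniq = np.unique(years)
        inside = uniq[period.mask(uniq)]
        if inside.size == 0:
            raise AttributionError(
                f"WBGT data has no years inside {period.start_year}-{period.end_year}"
            )
        wbgt_ds = wbgt_ds.isel(time=period.mask(years))
    pc = per_capita_whl_annual(wbgt_ds, sector, erf, workday)
    return pc.mean("year")


def economic_cost_hc(avoided_whl, unit_value) -> float | np.ndarray:
    """Human-capital economic value: avoided hours x unit value (USD/h).

    Both arguments may be scalars or aligned arrays (e.g. per-province
    avoided WHL with per-province wage rates); the result is the elementwise
    product (summable to a total by the caller).
    """
    uv = np.asarray(unit_value, dtype=float)
    if np.any(uv < 0):
        raise AttributionError("unit value must be >= 0")
    out = np.asarray(avoided_whl, dtype=float) * uv
    return out if out.ndim else float(out)
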