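"""Gridded exposed working population by sector.

From a gridded total population and per-province rates tables, the working
population per cell splits as

    agriculture     = total * rural_rate * agriculture_rate
    non-agriculture = total * urban_rate * non_agriculture_rate

with non-agriculture further divided into construction, manufacturing and
service by the province's sector split.  Indoor sectors (manufacturing,
service) are then reduced by the air-conditioning penetration rate to leave
the truly heat-exposed workers; outdoor sectors (agriculture, construction)
are unaffected.  Block regridding aggregates native-resolution rasters to
the analysis grid: population by sum (mass conserving), intensive fields
such as WBGT by mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

SECTORS = ("agriculture", "construction", "manufacturing", "service")
INDOOR_SECTORS = ("manufacturing", "service")
OUTDOOR_SECTORS = ("agriculture", "construction")


class ExposureError(ValueError):
    """Raised for inconsistent population/rates inputs."""


def _rates_lookup(rates: pd.DataFrame, names) -> dict:
    """province -> column -> year-indexed Series."""
    out = {}
    for name, grp in rates.groupby("province"):
        out[name] = grp.set_index("year")
    missing = set(names) - set(out)
    if missing:
        raise ExposureError(f"rates table missing province(s): {sorted(missing)}")
    return out


def working_population(
    pop: xr.DataArray,
    rates: pd.DataFrame,
    province_labels: np.ndarray,
    province_names: list[str],
) -> xr.Dataset:
    """Per-cell, per-sector working population (persons).

    ``pop`` has dims (year, y, x); ``province_labels`` assigns every cell an
    index into ``province_names`` (cell-center containment on the toy
    rectangular provinces).  Returns a Dataset with one variable per sector
    plus ``total_working``.
    """
    labels = np.asarray(province_labels)
    if labels.shape != pop.isel(year=0).shape:
        raise ExposureError(
            f"province raster {labels.shape} does not match grid "
            f"{pop.isel(year=0).shape}"
        )
    if labels.min() < 0 or labels.max() >= len(province_names):
        raise ExposureError(
            "province raster contains cells mapped to no province: indices "
            f"{np.argwhere((labels < 0) | (labels >= len(province_names)))[:10].tolist()}"
        )
    lut = _rates_lookup(rates, province_names)
    years = pop["year"].values
    for name in province_names:
        missing_years = set(years.tolist()) - set(lut[name].index)
        if missing_years:
            raise ExposureError(
                f"rates table for {name} missing year(s) {sorted(missing_years)[:5]}"
            )

    ny, nx = labels.shape
    out = {s: np.zeros((years.size, ny, nx)) for s in SECTORS}
    popv = pop.values
    for k, name in enumerate(province_names):
        mask = labels == k
        tab = lut[name].loc[years]
        urban = tab["urban_rate"].to_numpy()[:, None]
        rural = 1.0 - urban
        agri_rate = tab["agriculture_rate"].to_numpy()[:, None]
        nonagri_rate = tab["non_agriculture_rate"].to_numpy()[:, None]
        cell_pop = popv[:, mask]
        agri = cell_pop * rural * agri_rate
        nonagri = cell_pop * urban * nonagri_rate
        out["agriculture"][:, mask] = agri
        for sector, col in (
            ("construction", "construction_share"),
            ("manufacturing", "manufacturing_share"),
            ("service", "service_share"),
        ):
            out[sector][:, mask] = nonagri * tab[col].to_numpy()[:, None]

    coords = dict(pop.coords)
    ds = xr.Dataset(
        {s: (("year", "y", "x"), out[s]) for s in SECTORS}, coords=coords
    )
    ds["total_working"] = sum(ds[s] for s in SECTORS)
    ds.attrs["units"] = "persons"
    return ds


def apply_ac_adjustment(workers: xr.Dataset, ac_rate) -> xr.Dataset:
    """Remove AC-protected indoor workers from the exposed population.

    ``ac_rate`` may be a scalar or a per-year array aligned with the
    ``year`` coordinate.  Indoor sectors scale by (1 - ac_rate); outdoor
    sectors pass through unchanged.
    """
    ac = np.asarray(ac_rate, dtype=float)
    if np.any(ac < 0) or np.any(ac > 1):
        raise ExposureError(f"ac_rate must lie in [0, 1], got {ac_rate!r}")
    if ac.ndim == 1:
        if ac.size != workers.sizes["year"]:
            raise ExposureError("per-year ac_rate length does not match years")
        ac = xr.DataArray(ac, dims=("year",), coords={"year": workers["year"]})
    exposed = workers.copy()
    for s in INDOOR_SECTORS:
        exposed[s] = workers[s] * (1.0 - ac)
    exposed["total_working"] = workers["total_working"]
    exposed["total_exposed"] = sum(exposed[s] for s in SECTORS)
    exposed.attrs["ac_adjusted"] = "true"
    return exposed


def ac_rate_path(years, current_rate: float = 0.6, end_century_rate: float | None = None,
                 end_year: int = 2100, start_year: int = 2020) -> np.ndarray:
    """AC penetration path: constant, or a linear ramp to an end-century target."""
    y = np.asarray(years, dtype=float)
    if end_century_rate is None:
        return np.full(y.shape, current_rate)
    frac = np.clip((y - start_year) / (end_year - start_year), 0.0, 1.0)
    return current_rate + (end_century_rate - current_rate) * frac


def regrid(field: xr.DataArray, block: int, mode: str) -> xr.DataArray:
    """Aggregate ``block`` x ``block`` cells into one analysis cell.

    ``mode="sum"`` for extensive fields (population; mass conserving),
    ``mode="mean"`` for intensive fields (WBGT).  The grid must nest: both
    spatial dimensions divisible by ``block``.
    """
    if mode not in ("sum", "mean"):
        raise ExposureError(f"regrid mode must be 'sum' or 'mean', got {mode!r}")
    ny, nx = field.sizes["y"], field.sizes["x"]
    if ny % block or nx % block:
        raise ExposureError(
            f"grid {(ny, nx)} does not nest in blocks of {block}; "
            "general resampling is out of scope"
        )
    coarse = field.coarsen(y=block, x=block)
    out = coarse.sum() if mode == "sum" else coarse.mean()
    out.attrs = dict(field.attrs)
    out.attrs["regrid_block"] = block
    return out
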