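"""File adapters: NetCDF fields, CSV tables, YAML configs, labelled rasters.

NetCDF goes through xarray's scipy backend (NETCDF3 classic), which is
self-contained and round-trips every field the pipeline writes; 64-bit
integer coordinates are narrowed to 32-bit on write.  CSV schemas are
validated on read with the offending column named.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .erf import ERFParams, validate_workrest_table


class SchemaError(ValueError):
    """Raised when a file does not match its expected schema."""


def _netcdf3_safe(ds: xr.Dataset) -> xr.Dataset:
    ds = ds.copy()
    for name in list(ds.variables):
        if ds[name].dtype == np.int64:
            ds[name] = ds[name].astype(np.int32)
    ds.attrs = {k: v for k, v in ds.attrs.items() if isinstance(v, (str, int, float))}
    return ds


def write_netcdf(ds: xr.Dataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _netcdf3_safe(ds).to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


RATES_COLUMNS = (
    "province", "year", "urban_rate", "rural_rate", "agriculture_rate",
    "non_agriculture_rate", "construction_share", "manufacturing_share",
    "service_share", "ac_rate",
)
_RATE_COLS = RATES_COLUMNS[2:]


def write_rates_csv(rates: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rates[list(RATES_COLUMNS)].to_csv(path, index=False)
    return path


def read_rates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATES_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"rates CSV missing column(s): {sorted(missing)}")
    for col in _RATE_COLS:
        v = df[col].to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v > 1) or np.any(~np.isfinite(v)):
            raise SchemaError(f"column '{col}' must lie in [0, 1]")
    if np.any(np.abs(df["urban_rate"] + df["rural_rate"] - 1.0) > 1e-9):
        raise SchemaError("columns 'urban_rate' + 'rural_rate' must sum to 1")
    split = df[["construction_share", "manufacturing_share", "service_share"]].sum(axis=1)
    if np.any(np.abs(split - 1.0) > 1e-9):
        raise SchemaError(
            "columns 'construction_share'+'manufacturing_share'+'service_share' "
            "must sum to 1"
        )
    return df


def write_workrest_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[["intensity_w", "wbgt_c", "work_fraction"]].to_csv(path, index=False)
    return path


def read_workrest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"intensity_w", "wbgt_c", "work_fraction"} - set(df.columns)
    if missing:
        raise SchemaError(f"work/rest CSV missing column(s): {sorted(missing)}")
    try:
        validate_workrest_table(df)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return df


def write_erf_yaml(params: ERFParams, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(params.as_dict(), sort_keys=True))
    return path


def read_erf_yaml(path) -> ERFParams:
    d = yaml.safe_load(Path(path).read_text())
    try:
        return ERFParams.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed ERF YAML {path}: {exc}") from exc


def write_province_raster(labels: np.ndarray, names: list[str], path) -> Path:
    """Labelled province raster + name table as a small CSV pair-in-one.

    Stored as CSV: a header row of province names, then the integer label
    grid row by row.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, np.asarray(labels, dtype=int), fmt="%d", delimiter=",")
    return path


def read_province_raster(path) -> tuple[np.ndarray, list[str]]:
    lines = Path(path).read_text().strip().splitlines()
    names = lines[0].split(",")
    labels = np.array([[int(v) for v in ln.split(",")] for ln in lines[1:]], dtype=np.int32)
    if labels.min() < 0 or labels.max() >= len(names):
        bad = np.argwhere((labels < 0) | (labels >= len(names)))
        raise SchemaError(
            f"province raster has cells mapped to no province at indices "
            f"{bad[:10].tolist()}"
        )
    return labels, names


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
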