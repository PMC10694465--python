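"""Synthetic inputs for the labor-loss pipeline, with known ground truth.

Everything downstream stages consume can be generated here: gridded daily
meteorology per emission scenario and pseudo-GCM, a gridded working-age
population with a mid-century peak, per-province rates tables (urbanization,
sector shares, AC penetration) and work/rest tables drawn from a known
exposure-response curve.  All generators are deterministic given a seed.

The climate emulator is deliberately simple: a latitudinal temperature
gradient plus a sinusoidal seasonal cycle, a scenario-specific linear
warming trend (flat after a stabilization year for the low-emission and
1.5 degC scenarios), and AR(1) daily weather noise.  It reproduces the
gross features projections of this kind rely on - scenario-ordered warming,
seasonality, spatial gradients, inter-model spread - not the covariance
structure of any real model ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

DAYS_PER_YEAR = 365  # no-leap calendar, as in typical climate-model output

#: scenario presets: (warming rate degC/decade at end of century, stabilization year)
SCENARIO_PRESETS = {
    "rcp26": (0.2, 2050),
    "rcp45": (0.35, None),
    "rcp85": (0.5, None),
    "cool15": (0.2, 2035),
}


class ConfigError(ValueError):
    """Raised for invalid synthetic-data configuration."""


@dataclass(frozen=True)
class ProvinceLayout:
    """Axis-aligned rectangular partition of the grid into toy provinces.

    ``n_rows`` x ``n_cols`` blocks; block (i, j) is province ``P{i}{j}``.
    """

    n_rows: int = 2
    n_cols: int = 2

    def names(self) -> list[str]:
        return [f"P{i}{j}" for i in range(self.n_rows) for j in range(self.n_cols)]

    def labels(self, grid_shape: tuple[int, int]) -> np.ndarray:
        """Integer label raster (rows x cols); label k = names()[k]."""
        ny, nx = grid_shape
        if ny % self.n_rows or nx % self.n_cols:
            raise ConfigError(
                f"grid {grid_shape} does not partition into "
                f"{self.n_rows}x{self.n_cols} provinces"
            )
        by, bx = ny // self.n_rows, nx // self.n_cols
        rows = np.arange(ny) // by
        cols = np.arange(nx) // bx
        return (rows[:, None] * self.n_cols + cols[None, :]).astype(np.int32)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic study domain.

    The grid is ``grid_shape`` cells of ``cell_size_km``; ``years`` spans
    ``year_start``..``year_end`` inclusive, sampled every ``year_step`` years
    (each sampled year carries a full 365-day calendar).  ``warming_rate`` is
    the linear trend in degC per decade reached by end of century, flat after
    ``stabilization_year`` where set.
    """

    grid_shape: tuple[int, int] = (8, 8)
    cell_size_km: float = 50.0
    year_start: int = 1986
    year_end: int = 2100
    year_step: int = 1
    scenario_id: str = "rcp85"
    warming_rate: float | None = None   # degC/decade; None -> scenario preset
    stabilization_year: int | None = None
    n_pseudo_gcms: int = 2
    seed: int = 0
    province_layout: ProvinceLayout = field(default_factory=ProvinceLayout)
    # climate shape parameters
    base_temp_c: float = 9.0         # grid-mean annual-mean temperature, start of record
    lat_gradient_c: float = 8.0      # north-south annual-mean contrast across the grid
    seasonal_amplitude_c: float = 10.0
    diurnal_half_range_c: float = 4.0
    ar1_coef: float = 0.7            # daily weather persistence
    noise_sd_c: float = 2.0
    humidity_base_pct: float = 70.0
    humidity_temp_coef: float = -1.0  # % RH per degC of temperature anomaly
    wind_mean_ms: float = 2.0
    rsds_mean_wm2: float = 220.0
    rsds_seasonal_wm2: float = 80.0
    trend_reference_year: int = 2006  # warming measured from the end of the baseline
    gcm_trend_spread: float = 0.05    # fractional trend perturbation per pseudo-GCM

    def __post_init__(self) -> None:
        if self.year_end < self.year_start or self.year_step < 1:
            raise ConfigError("years must be a non-empty inclusive range")
        if min(self.grid_shape) < 1:
            raise ConfigError("grid_shape must be positive")
        if self.n_pseudo_gcms < 1:
            raise ConfigError("need at least one pseudo-GCM")
        if self.scenario_id not in SCENARIO_PRESETS:
            raise ConfigError(
                f"unknown scenario {self.scenario_id!r}; "
                f"expected one of {sorted(SCENARIO_PRESETS)}"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1, self.year_step)

    def trend_params(self) -> tuple[float, int | None]:
        preset_rate, preset_stab = SCENARIO_PRESETS[self.scenario_id]
        rate = preset_rate if self.warming_rate is None else self.warming_rate
        stab = preset_stab if self.stabilization_year is None else self.stabilization_year
        return rate, stab

    def for_scenario(self, scenario_id: str) -> "SyntheticConfig":
        """Same domain and seed under another emission scenario."""
        return replace(self, scenario_id=scenario_id,
                       warming_rate=None, stabilization_year=None)


def trend_offset(cfg: SyntheticConfig, years) -> np.ndarray:
    """Scenario warming (degC) added to each year's temperatures."""
    rate, stab = cfg.trend_params()
    y = np.asarray(years, dtype=float)
    if stab is not None:
        y = np.minimum(y, stab)
    return rate / 10.0 * (y - cfg.trend_reference_year)


def generate_climate(cfg: SyntheticConfig) -> xr.Dataset:
    """Gridded daily meteorology for all years and pseudo-GCMs of ``cfg``.

    Returns a Dataset with variables ``tas``, ``tasmax``, ``hurs``,
    ``sfcWind``, ``rsds`` over dims ``(gcm, time, y, x)`` and coordinates
    ``year``/``doy`` along ``time``.  Physical invariants hold by
    construction: tasmax >= tas, hurs in [0, 100], wind and rsds >= 0.
    """
    ny, nx = cfg.grid_shape
    years = cfg.years
    nyrs = years.size
    ntime = nyrs * DAYS_PER_YEAR
    doy = np.tile(np.arange(DAYS_PER_YEAR), nyrs)
    year_of_day = np.repeat(years, DAYS_PER_YEAR)

    # deterministic spatial/seasonal structure
    lat = np.linspace(cfg.lat_gradient_c / 2.0, -cfg.lat_gradient_c / 2.0, ny)
    base = cfg.base_temp_c + lat[:, None] + np.zeros((ny, nx))
    season = -cfg.seasonal_amplitude_c * np.cos(2.0 * np.pi * (doy - 15) / DAYS_PER_YEAR)

    gcm_fields = {v: [] for v in ("tas", "tasmax", "hurs", "sfcWind", "rsds")}
    for g in range(cfg.n_pseudo_gcms):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, g, _scen_code(cfg)]))
        trend_scale = 1.0 + cfg.gcm_trend_spread * (g - (cfg.n_pseudo_gcms - 1) / 2.0)
        trend = trend_offset(cfg, year_of_day) * trend_scale

        noise = _ar1(rng, cfg.ar1_coef, cfg.noise_sd_c, (ntime, ny, nx))
        anom = season[:, None, None] + trend[:, None, None] + noise
        tas = base[None, :, :] + anom
        tasmax = tas + cfg.diurnal_half_range_c + rng.gamma(2.0, 0.5, (ntime, ny, nx))
        hurs = np.clip(
            cfg.humidity_base_pct
            + cfg.humidity_temp_coef * (anom - season[:, None, None])
            + rng.normal(0.0, 5.0, (ntime, ny, nx)),
            0.0, 100.0,
        )
        wind = np.maximum(rng.gamma(4.0, cfg.wind_mean_ms / 4.0, (ntime, ny, nx)), 0.0)
        rsds = np.clip(
            cfg.rsds_mean_wm2
            - cfg.rsds_seasonal_wm2 * np.cos(2.0 * np.pi * (doy - 15) / DAYS_PER_YEAR)[:, None, None]
            + rng.normal(0.0, 30.0, (ntime, ny, nx)),
            0.0, None,
        )
        for name, arr in zip(gcm_fields, (tas, tasmax, hurs, wind, rsds)):
            gcm_fields[name].append(arr)

    coords = {
        "gcm": [f"pgcm{g}" for g in range(cfg.n_pseudo_gcms)],
        "time": np.arange(ntime),
        "year": ("time", year_of_day),
        "doy": ("time", doy),
        "y": np.arange(ny),
        "x": np.arange(nx),
    }
    ds = xr.Dataset(
        {
            name: (("gcm", "time", "y", "x"), np.stack(arrs).astype(np.float64))
            for name, arrs in gcm_fields.items()
        },
        coords=coords,
        attrs={
            "scenario_id": cfg.scenario_id,
            "cell_size_km": cfg.cell_size_km,
            "calendar": "noleap",
            "seed": cfg.seed,
        },
    )
    ds["tas"].attrs["units"] = ds["tasmax"].attrs["units"] = "degC"
    ds["hurs"].attrs["units"] = "%"
    ds["sfcWind"].attrs["units"] = "m s-1"
    ds["rsds"].attrs["units"] = "W m-2"
    return ds


def _scen_code(cfg: SyntheticConfig) -> int:
    # pseudo-GCM weather noise is shared across scenarios so differences
    # between scenarios are the forced trend, as in bias-corrected ensembles
    return 0


def _ar1(rng, rho, sd, shape):
    """AR(1) process along axis 0 with stationary marginal sd."""
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), shape)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, shape[1:])
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + eps[t]
    return out


# ---------------------------------------------------------------------------
# population and rates tables

FERTILITY_SCENARIOS = ("low", "moderate", "high")


def fertility_multiplier(scenario: str, years) -> np.ndarray:
    """Scalar population multiplier path per fertility scenario.

    ``moderate`` is 1; ``low``/``high`` ramp linearly to 0.9/1.1 of the
    moderate path by 2100, diverging after 2030 (near-term cohorts are
    already born).
    """
    if scenario not in FERTILITY_SCENARIOS:
        raise ConfigError(f"unknown fertility scenario {scenario!r}")
    y = np.asarray(years, dtype=float)
    ramp = np.clip((y - 2030.0) / (2100.0 - 2030.0), 0.0, 1.0)
    delta = {"low": -0.1, "moderate": 0.0, "high": 0.1}[scenario]
    return 1.0 + delta * ramp


def generate_population_inputs(
    cfg: SyntheticConfig,
    peak_year: int = 2030,
    peak_total: float = 0.75e9,
    decline_width_years: float = 85.0,
) -> tuple[xr.DataArray, pd.DataFrame]:
    """Gridded annual population plus per-province annual rates tables.

    The national total follows a Gaussian-in-time path peaking at
    ``peak_total`` in ``peak_year`` (rising through the early century,
    declining in the second half); the spatial pattern is a fixed lognormal
    weight field.  The rates table carries, per province-year: a rising
    urban_rate (logistic), time-constant agriculture_rate and
    non_agriculture_rate, a non-agriculture sector split
    (construction/manufacturing/service) and an ac_rate.
    """
    years = cfg.years
    if not (years[0] <= peak_year <= years[-1]):
        raise ConfigError(
            f"peak_year {peak_year} outside the configured years "
            f"{years[0]}..{years[-1]}"
        )
    ny, nx = cfg.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_001]))
    weights = rng.lognormal(0.0, 1.0, (ny, nx))
    weights /= weights.sum()
    national = peak_total * np.exp(-(((years - peak_year) / decline_width_years) ** 2))
    pop = xr.DataArray(
        national[:, None, None] * weights[None, :, :],
        dims=("year", "y", "x"),
        coords={"year": years, "y": np.arange(ny), "x": np.arange(nx)},
        name="total_pop",
        attrs={"units": "persons", "native_resolution_km": cfg.cell_size_km},
    )

    labels = cfg.province_layout.labels(cfg.grid_shape)
    names = cfg.province_layout.names()
    rows = []
    for k, name in enumerate(names):
        prng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20_000 + k]))
        u0 = prng.uniform(0.45, 0.65)          # urban share today
        u_end = prng.uniform(0.75, 0.85)       # end-century urban share
        agri = prng.uniform(0.4, 0.6)          # working share of rural pop
        nonagri = prng.uniform(0.5, 0.6)       # working share of urban pop
        split = np.array([0.15, 0.35, 0.50])   # construction/manufacturing/service
        t = (years - years[0]) / max(years[-1] - years[0], 1)
        urban = u0 + (u_end - u0) / (1.0 + np.exp(-8.0 * (t - 0.4)))
        urban = np.clip(urban, 0.0, 1.0)
        for yi, year in enumerate(years):
            rows.append(
                {
                    "province": name,
                    "year": int(year),
                    "urban_rate": urban[yi],
                    "rural_rate": 1.0 - urban[yi],
                    "agriculture_rate": agri,
                    "non_agriculture_rate": nonagri,
                    "construction_share": split[0],
                    "manufacturing_share": split[1],
                    "service_share": split[2],
                    "ac_rate": 0.6,
                }
            )
    rates = pd.DataFrame(rows)
    rates.attrs["province_labels"] = labels
    rates.attrs["province_names"] = names
    return pop, rates


def generate_workrest_table(
    params, wbgt_points, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Work/rest table (intensity_w, wbgt_c, work_fraction) from a known ERF.

    ``work_fraction = 1 - loss_fraction(wbgt) + noise``, clipped to [0, 1];
    noiseless tables let the CDF fit be checked against the generating truth.
    """
    from .erf import INTENSITIES, loss_fraction

    pts = np.asarray(wbgt_points, dtype=float)
    if np.unique(pts).size < 4:
        raise ConfigError("need >= 4 distinct WBGT points per intensity")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for intensity in INTENSITIES:
        wf = 1.0 - loss_fraction(pts, intensity, params)
        if noise_sd > 0:
            wf = wf + rng.normal(0.0, noise_sd, pts.shape)
        wf = np.clip(wf, 0.0, 1.0)
        for w, f in zip(pts, wf):
            rows.append({"intensity_w": intensity, "wbgt_c": w, "work_fraction": f})
    return pd.DataFrame(rows)
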