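"""Daily bidirectional coupling of soil water and the stress predictor.

Each day, per land-cover fraction: the soil column's plant available water
joins the meteorological covariates; the stress predictor (learned network
in hybrid mode, the process formula in process mode — both behind the same
``predict_stress`` interface) converts potential to actual transpiration;
bare-soil evaporation and interception complete the flux; and the column is
updated with the extraction, so tomorrow's stress sees today's drawdown.

Land cover is handled as independent per-unit-area columns: tall vegetation
(three soil layers), short vegetation and bare soil (two layers each). The
stress multiplies potential transpiration *before* fraction weighting, and
cell totals are the fraction-weighted sums. Covariate anomalies come from a
climatology precomputed over the forcing archive (a process-mode pass for
PAW), which keeps the daily step a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pet
from .prep import COVARIATES, doy_climatology
from .soil import SoilParams, SoilState, initial_state, step_water_balance
from .stress_process import ProcessStressModel, StressParams, compute_vodmax, process_sb
from .synthetic import SiteMeta

__all__ = [
    "ModelRunConfig",
    "Climatology",
    "precompute_climatology",
    "make_process_models",
    "step_day",
    "run",
    "run_grid",
]

_COLUMNS = ("tall", "short", "bare")


@dataclass(frozen=True)
class ModelRunConfig:
    """Configuration of a coupled run."""

    mode: str = "hybrid"  # "hybrid" or "process"
    site: SiteMeta = field(default_factory=SiteMeta)
    alpha_pt: float = pet.ALPHA_PT
    interception_on: bool = True
    interception_coef: float = 0.2
    rain_threshold_mm: float = pet.DEFAULT_RAIN_THRESHOLD_MM
    e_w_mm: float = 0.0  # open-water evaporation, constant stub
    e_s_mm: float = 0.0  # snow sublimation, constant stub
    #: under-canopy surface-evaporation demand in vegetated columns, as a
    #: fraction of potential evaporation (same drying term the synthetic
    #: world applies); a diagnostic flux, not part of E_total
    soil_evap_frac: float = 0.3
    soil_tall: SoilParams = field(default_factory=SoilParams.tall)
    soil_short: SoilParams = field(default_factory=SoilParams.short)
    anomaly_window_days: int = 31

    def __post_init__(self) -> None:
        if self.mode not in ("hybrid", "process"):
            raise ValueError("mode must be 'hybrid' or 'process'")

    def soil_params(self, column: str) -> SoilParams:
        return self.soil_tall if column == "tall" else self.soil_short


@dataclass
class Climatology:
    """Day-of-year climatologies used to form covariate anomalies during a
    coupled run: one per driver, plus PAW per vegetation class."""

    drivers: dict  # name -> Series indexed 1..365
    paw: dict  # veg class -> Series indexed 1..365

    def anomalies(self, doy: int, absolutes: dict, veg_class: str) -> dict:
        d = min(doy, 365)
        out = {}
        for name in COVARIATES:
            clim = self.paw[veg_class] if name == "PAW" else self.drivers[name]
            out[f"{name}_anom"] = absolutes[name] - float(clim.loc[d])
        return out


def _process_mode_paw_series(forcing: pd.DataFrame, cfg: "ModelRunConfig", column: str) -> pd.Series:
    """PAW series from a water-balance pass with process-formula stress."""
    params = cfg.soil_params(column)
    vod_max = compute_vodmax(forcing["VOD"].to_numpy())
    model = ProcessStressModel(StressParams(vod_max=vod_max, soil=params))
    state = initial_state(params, w0=0.5 * (params.w_wp + params.w_c))
    ept = pet.priestley_taylor(forcing["Rn"].to_numpy(), forcing["Ta"].to_numpy(), cfg.alpha_pt)
    paw = np.empty(len(forcing))
    for i, (_, f) in enumerate(forcing.iterrows()):
        paw[i] = state.paw(params)
        st = model.predict_stress({"VOD": float(f["VOD"]), "w_w": state.w_w})
        e_i = pet.interception_simple(float(f["P"]), float(f["LAI"]), cfg.interception_coef) if cfg.interception_on else 0.0
        e_b = cfg.soil_evap_frac * process_sb(state.w_1, params) * ept[i]
        res = step_water_balance(state, max(float(f["P"]) - e_i, 0.0), st * ept[i], e_b, params)
        state = res.state
    return pd.Series(paw, index=forcing.index)


def precompute_climatology(forcing: pd.DataFrame, cfg: ModelRunConfig) -> Climatology:
    """Build the anomaly climatology from the forcing archive.

    Driver climatologies come straight from the forcing; the PAW
    climatology per vegetation class comes from a process-mode
    water-balance pass over the archive (no learned model involved, so
    hybrid and process runs share identical anomalies).
    """
    drivers = {
        name: doy_climatology(forcing[name].astype(float), cfg.anomaly_window_days)
        for name in COVARIATES
        if name != "PAW"
    }
    paw = {
        veg: doy_climatology(
            _process_mode_paw_series(forcing, cfg, veg), cfg.anomaly_window_days
        )
        for veg in ("tall", "short")
    }
    return Climatology(drivers=drivers, paw=paw)


def make_process_models(forcing: pd.DataFrame, cfg: ModelRunConfig) -> dict:
    """Process-formula stress predictors for both vegetation classes, with
    VOD_max taken as the 99th percentile of the forcing archive."""
    vod_max = compute_vodmax(forcing["VOD"].to_numpy())
    return {
        "tall": ProcessStressModel(StressParams(vod_max=vod_max, soil=cfg.soil_tall)),
        "short": ProcessStressModel(StressParams(vod_max=vod_max, soil=cfg.soil_short)),
    }


def step_day(
    forcing_row: pd.Series,
    doy: int,
    soils: dict,
    stress_models: dict,
    cfg: ModelRunConfig,
    clim: Climatology,
) -> tuple[dict, dict]:
    """One daily step: fluxes out, updated soil columns back.

    ``soils`` maps 'tall'/'short'/'bare' to SoilState; ``stress_models``
    maps 'tall'/'short' to any object with ``predict_stress(covariates)``.
    Returns ``(diagnostics, new_soils)``; pure given its inputs.
    """
    site = cfg.site
    P = float(forcing_row["P"])
    ept = pet.priestley_taylor(float(forcing_row["Rn"]), float(forcing_row["Ta"]), cfg.alpha_pt)

    e_i_unit = (
        pet.interception_simple(P, float(forcing_row["LAI"]), cfg.interception_coef)
        if cfg.interception_on
        else 0.0
    )
    p_veg = max(P - e_i_unit, 0.0)

    diag: dict = {"E_pt": ept, "E_i": e_i_unit * (site.frac_tall + site.frac_short)}
    new_soils: dict = {}

    for veg in ("tall", "short"):
        params = cfg.soil_params(veg)
        state = soils[veg]
        absolutes = {
            "PAW": state.paw(params),
            "VPD": float(forcing_row["VPD"]),
            "Ta": float(forcing_row["Ta"]),
            "SWi": float(forcing_row["SWi"]),
            "VOD": float(forcing_row["VOD"]),
            "CO2": float(forcing_row["CO2"]),
        }
        cov = dict(absolutes)
        cov.update(clim.anomalies(doy, absolutes, veg))
        cov["w_w"] = state.w_w
        cov["w_1"] = state.w_1
        st = float(np.clip(stress_models[veg].predict_stress(cov), 0.0, 1.0))
        e_b_demand = cfg.soil_evap_frac * process_sb(state.w_1, params) * ept
        res = step_water_balance(state, p_veg, st * ept, e_b_demand, params)
        new_soils[veg] = res.state
        diag[f"S_t_{veg}"] = st
        diag[f"PAW_{veg}"] = absolutes["PAW"]
        diag[f"E_t_{veg}"] = res.e_t_actual_mm
        diag[f"E_b_{veg}"] = res.e_b_actual_mm
        diag[f"drainage_{veg}"] = res.drainage_mm
        diag[f"storage_{veg}"] = res.state.storage_mm(params)
        diag[f"shortfall_{veg}"] = res.shortfall_mm

    # bare-soil column: soil evaporation only, full precipitation input
    params_b = cfg.soil_short
    state_b = soils["bare"]
    sb = process_sb(state_b.w_1, params_b)
    res_b = step_water_balance(state_b, P, 0.0, sb * ept, params_b)
    new_soils["bare"] = res_b.state
    diag["S_b"] = sb
    diag["E_b"] = res_b.e_b_actual_mm
    diag["drainage_bare"] = res_b.drainage_mm
    diag["storage_bare"] = res_b.state.storage_mm(params_b)

    diag["E_w"] = cfg.e_w_mm * site.frac_water
    diag["E_s"] = cfg.e_s_mm
    diag["E_total"] = (
        site.frac_tall * diag["E_t_tall"]
        + site.frac_short * diag["E_t_short"]
        + site.frac_bare * diag["E_b"]
        + diag["E_i"]
        + diag["E_w"]
        + diag["E_s"]
    )
    return diag, new_soils


def run(
    forcing: pd.DataFrame,
    cfg: ModelRunConfig,
    stress_models: dict | None = None,
    clim: Climatology | None = None,
    initial_soils: dict | None = None,
) -> pd.DataFrame:
    """Sequential daily coupled run over a forcing series.

    In process mode the stress predictors default to the process formula; in
    hybrid mode trained models must be supplied as
    ``{"tall": model, "short": model}``. The forcing index must be daily and
    gap-free — missing days raise rather than being silently interpolated.
    """
    idx = forcing.index
    if not isinstance(idx, pd.DatetimeIndex) or len(idx) == 0:
        raise ValueError("forcing needs a non-empty DatetimeIndex")
    expected = pd.date_range(idx[0], idx[-1], freq="D")
    if not idx.equals(expected):
        missing = expected.difference(idx)
        raise ValueError(f"forcing has {len(missing)} missing days, first: {missing[0].date()}")

    if stress_models is None:
        if cfg.mode != "process":
            raise ValueError("hybrid mode requires trained stress models")
        stress_models = make_process_models(forcing, cfg)
    clim = clim or precompute_climatology(forcing, cfg)

    def _mid(p: SoilParams) -> SoilState:
        return initial_state(p, w0=0.5 * (p.w_wp + p.w_c))

    soils = initial_soils or {
        "tall": _mid(cfg.soil_tall),
        "short": _mid(cfg.soil_short),
        "bare": _mid(cfg.soil_short),
    }
    rows = []
    for date, f in forcing.iterrows():
        diag, soils = step_day(f, int(date.dayofyear), soils, stress_models, cfg, clim)
        diag["P"] = float(f["P"])
        rows.append(diag)
    return pd.DataFrame(rows, index=idx)


def run_grid(ds, cfg: ModelRunConfig, stress_models: dict | None = None):
    """Coupled run over a gridded forcing Dataset (time, y, x): cells are
    independent and iterated one by one. Returns a Dataset of the main
    outputs with the same grid."""
    import xarray as xr

    out_vars = ["E_total", "E_t_tall", "E_t_short", "E_b", "E_i", "S_t_tall", "S_t_short",
                "PAW_tall", "PAW_short"]
    ny, nx = ds.sizes["y"], ds.sizes["x"]
    time = ds.indexes["time"]
    acc = {v: np.empty((len(time), ny, nx)) for v in out_vars}
    for iy in range(ny):
        for ix in range(nx):
            cell = pd.DataFrame(
                {v: ds[v].isel(y=iy, x=ix).to_numpy() for v in ds.data_vars}, index=time
            )
            res = run(cell, cfg, stress_models)
            for v in out_vars:
                acc[v][:, iy, ix] = res[v].to_numpy()
    return xr.Dataset(
        {
            v: xr.DataArray(
                acc[v],
                dims=("time", "y", "x"),
                coords={"time": time, "y": ds["y"], "x": ds["x"]},
                attrs={"units": "mm/day" if v.startswith("E") else "1"},
            )
            for v in out_vars
        }
    )
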