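"""Seeded synthetic site and grid worlds.

Every other module is testable without downloads because this module
fabricates the whole observing system: daily meteorological forcing with
seasonal cycles and a two-state rain process, a known smooth ground-truth
transpiration stress function of the six covariates, soil moisture evolved
with a real water balance, and noisy pseudo-observations of evaporation and
per-tree sap flow. The embedded truth function is what the learned stress
model must recover, so generation keeps it alongside the observations.

The truth stress is a product of physiologically shaped factors: logistic in
plant available water, exponential decay in vapour pressure deficit, a
thermal optimum curve, light saturation in shortwave radiation, a
sqrt(VOD/VOD_max) phenology factor and a weak CO2 response — smooth, bounded
in [0, 1], and exercising every covariate.

What this world does **not** emulate: satellite retrieval error structures,
energy-balance closure gaps of real towers, or the climatology of any
specific biome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pet
from .prep import CM3_PER_M2_TO_MM, crown_area
from .soil import SoilParams, initial_state, step_water_balance
from .stress_process import process_sb

__all__ = [
    "ClimateParams",
    "TruthStressSpec",
    "SiteMeta",
    "generate_forcing",
    "generate_observations",
    "generate_sapflow_table",
    "make_training_world",
    "generate_grid_world",
]


@dataclass(frozen=True)
class ClimateParams:
    """Knobs of the forcing generator (temperate defaults)."""

    mat_C: float = 12.0  # mean annual temperature
    ta_amplitude_C: float = 9.0
    ta_noise_C: float = 2.0
    swi_mean_wm2: float = 180.0
    swi_amplitude_wm2: float = 110.0
    rn_fraction: float = 0.6  # net/incoming shortwave ratio
    wet_prob_after_dry: float = 0.12
    wet_prob_after_wet: float = 0.45
    mean_rain_mm: float = 5.0
    vod_mean: float = 0.6
    vod_amplitude: float = 0.25
    lai_mean: float = 2.5
    lai_amplitude: float = 1.5
    co2_base_ppm: float = 410.0
    co2_trend_ppm_per_yr: float = 2.3
    bare_evap_frac: float = 0.3  # soil-evaporation demand as a fraction of E_p


@dataclass(frozen=True)
class TruthStressSpec:
    """Known ground-truth stress function and observation noise.

    Deterministic given its parameters; output clamped to [0, 1].
    """

    paw_k: float = 8.0  # logistic steepness in PAW
    paw_mid: float = 0.35  # logistic midpoint
    vpd_decay_kpa: float = 0.35  # exponential decay rate in VPD
    ta_opt_C: float = 20.0
    ta_sigma_C: float = 14.0
    swi_half_wm2: float = 60.0  # light half-saturation
    vod_max: float = 1.0
    co2_sens: float = -0.05  # weak fractional response per 100 ppm above 400
    noise_sd_mm: float = 0.05  # additive Gaussian noise on observed E, mm/day
    constant: float | None = None  # override: a constant stress (for tests)

    def stress(self, PAW, VPD, Ta, SWi, VOD, CO2):
        """Truth S_t in [0, 1] from the six absolute covariates."""
        if self.constant is not None:
            shape = np.broadcast(
                np.asarray(PAW), np.asarray(VPD), np.asarray(Ta),
                np.asarray(SWi), np.asarray(VOD), np.asarray(CO2),
            ).shape
            return np.full(shape, float(np.clip(self.constant, 0.0, 1.0)))
        paw_f = 1.0 / (1.0 + np.exp(-self.paw_k * (np.asarray(PAW, float) - self.paw_mid)))
        vpd_f = np.exp(-self.vpd_decay_kpa * np.asarray(VPD, float))
        ta_f = np.exp(-(((np.asarray(Ta, float) - self.ta_opt_C) / self.ta_sigma_C) ** 2))
        swi = np.asarray(SWi, float)
        swi_f = swi / (swi + self.swi_half_wm2)
        vod_f = np.sqrt(np.clip(np.asarray(VOD, float) / self.vod_max, 0.0, 1.0))
        co2_f = 1.0 + self.co2_sens * (np.asarray(CO2, float) - 400.0) / 100.0
        return np.clip(paw_f * vpd_f * ta_f * swi_f * vod_f * co2_f, 0.0, 1.0)


@dataclass(frozen=True)
class SiteMeta:
    """Site identity and land-cover composition."""

    site_id: str = "SYN-000"
    veg_class: str = "tall"  # "tall" or "short"
    frac_tall: float = 0.7
    frac_short: float = 0.2
    frac_bare: float = 0.1
    frac_water: float = 0.0
    mat_C: float = 12.0
    map_mm: float = 900.0

    def __post_init__(self) -> None:
        fr = (self.frac_tall, self.frac_short, self.frac_bare, self.frac_water)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-9:
            raise ValueError("cover fractions must lie in [0,1] and sum to at most 1")
        if self.veg_class not in ("tall", "short"):
            raise ValueError("veg_class must be 'tall' or 'short'")


def _svp_kpa(Ta):
    return 0.6108 * np.exp(17.27 * Ta / (Ta + 237.3))


def generate_forcing(
    seed: int,
    n_days: int,
    climate: ClimateParams = ClimateParams(),
    start: str = "2015-01-01",
) -> pd.DataFrame:
    """Daily forcing with seasonal cycles and Markov-chain rainfall.

    Returns a frame indexed by date with columns P, Rn, Ta, VPD, SWi, VOD,
    CO2, LAI. Identical seeds give bit-identical output.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    t = np.arange(n_days)
    season = np.sin(2 * np.pi * (doy - 81) / 365.25)  # peaks near the solstice

    # rain occurrence: first-order two-state chain, exponential depths
    wet = np.zeros(n_days, dtype=bool)
    u = rng.random(n_days)
    state = False
    for i in range(n_days):
        p = climate.wet_prob_after_wet if state else climate.wet_prob_after_dry
        state = u[i] < p
        wet[i] = state
    P = np.where(wet, rng.exponential(climate.mean_rain_mm, n_days), 0.0)

    # temperature: seasonal cycle + AR(1) noise
    eps = rng.normal(0, climate.ta_noise_C, n_days)
    ar = np.empty(n_days)
    acc = 0.0
    for i in range(n_days):
        acc = 0.7 * acc + eps[i]
        ar[i] = acc
    Ta = climate.mat_C + climate.ta_amplitude_C * season + ar

    # shortwave: seasonal cycle dimmed on wet (cloudy) days
    cloud = np.where(wet, rng.uniform(0.35, 0.75, n_days), rng.uniform(0.8, 1.0, n_days))
    SWi = np.maximum((climate.swi_mean_wm2 + climate.swi_amplitude_wm2 * season) * cloud, 0.0)
    Rn = np.maximum(climate.rn_fraction * SWi + rng.normal(0, 5, n_days), 0.0)

    # humidity: wet days are moist; VPD from saturation deficit
    rh = np.clip(0.62 + 0.12 * np.where(wet, 1.0, -1.0) + rng.normal(0, 0.08, n_days), 0.25, 0.98)
    VPD = np.maximum(_svp_kpa(Ta) * (1.0 - rh), 0.0)

    # vegetation phenology: VOD and LAI track the growing season
    VOD = np.maximum(climate.vod_mean + climate.vod_amplitude * season + rng.normal(0, 0.03, n_days), 0.02)
    LAI = np.maximum(climate.lai_mean + climate.lai_amplitude * season + rng.normal(0, 0.1, n_days), 0.05)

    CO2 = (
        climate.co2_base_ppm
        + climate.co2_trend_ppm_per_yr * t / 365.25
        - 2.5 * season
        + rng.normal(0, 0.3, n_days)
    )

    return pd.DataFrame(
        {"P": P, "Rn": Rn, "Ta": Ta, "VPD": VPD, "SWi": SWi, "VOD": VOD, "CO2": CO2, "LAI": LAI},
        index=dates,
    )


def generate_observations(
    forcing: pd.DataFrame,
    truth: TruthStressSpec = TruthStressSpec(),
    soil_params: SoilParams | None = None,
    seed: int = 0,
    interception_coef: float = 0.2,
    climate: ClimateParams = ClimateParams(),
) -> pd.DataFrame:
    """Evolve soil moisture under the forcing and emit pseudo-observations.

    Day by day: potential evaporation from Priestley-Taylor, truth stress
    from the current covariates (PAW read from the evolving soil column),
    true transpiration E_t = S_t * E_pt, observed evaporation
    ``E_obs = E_t + noise`` on dry days with an added interception-like term
    on rain days. The soil is updated with the resulting extraction, so PAW
    feeds back on the stress exactly as in the coupled model.

    Returns the forcing plus columns w_w, w_1, PAW, E_pt_raw, S_t_true,
    E_t_true, E_obs.
    """
    if len(forcing) == 0:
        raise ValueError("forcing is empty")
    soil_params = soil_params or SoilParams.tall()
    rng = np.random.default_rng(seed)
    # start midway between wilting point and critical moisture (PAW = 0.5)
    state = initial_state(soil_params, w0=0.5 * (soil_params.w_wp + soil_params.w_c))

    ept = pet.priestley_taylor(forcing["Rn"].to_numpy(), forcing["Ta"].to_numpy())
    noise = rng.normal(0.0, truth.noise_sd_mm, len(forcing)) if truth.noise_sd_mm > 0 else np.zeros(len(forcing))

    rows = []
    for i, (_, f) in enumerate(forcing.iterrows()):
        paw = state.paw(soil_params)
        st = float(truth.stress(paw, f["VPD"], f["Ta"], f["SWi"], f["VOD"], f["CO2"]))
        e_t = st * ept[i]
        e_i = pet.interception_simple(float(f["P"]), float(f["LAI"]), interception_coef)
        e_b = climate.bare_evap_frac * process_sb(state.w_1, soil_params) * ept[i]
        e_obs = max(e_t + e_i + noise[i], 0.0)
        rows.append(
            {
                "w_w": state.w_w,
                "w_1": state.w_1,
                "PAW": paw,
                "E_pt_raw": ept[i],
                "S_t_true": st,
                "E_t_true": e_t,
                "E_i_true": e_i,
                "E_obs": e_obs,
            }
        )
        res = step_water_balance(state, max(float(f["P"]) - e_i, 0.0), e_t, e_b, soil_params)
        state = res.state

    obs = pd.DataFrame(rows, index=forcing.index)
    return pd.concat([forcing, obs], axis=1)


def generate_sapflow_table(
    n_trees: int,
    n_days: int,
    site: SiteMeta = SiteMeta(),
    truth: TruthStressSpec = TruthStressSpec(),
    seed: int = 0,
    species_pool: tuple[str, ...] = ("Fagus sylvatica", "Picea abies", "Quercus robur"),
    tree_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tree hourly sap-flow volumes consistent with a known stand
    transpiration.

    The stand transpiration is truth S_t x E_pt from a coupled synthetic
    site run; each tree's daily sap-flow volume is that flux times its
    allometric crown area (times an optional lognormal tree factor of mean
    one), spread over the day with a daylight-weighted diurnal profile.

    Returns ``(table, site_series)``: the long-format table with columns
    date, tree_id, species, A_b, sapflow_cm3h, and the underlying site
    series carrying the stand truth.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be at least 1")
    rng = np.random.default_rng(seed)
    climate = ClimateParams(mat_C=site.mat_C)
    forcing = generate_forcing(seed, n_days, climate)
    soil = SoilParams.tall() if site.veg_class == "tall" else SoilParams.short()
    series = generate_observations(forcing, truth, soil, seed=seed + 1, climate=climate)
    stand_et = series["E_t_true"].to_numpy()

    ab = rng.lognormal(mean=np.log(0.05), sigma=0.5, size=n_trees)  # basal areas, m2
    species = rng.choice(species_pool, size=n_trees)
    ac = crown_area(ab, site.mat_C, site.map_mm)
    tree_factor = (
        rng.lognormal(mean=-0.5 * tree_noise_sd**2, sigma=tree_noise_sd, size=n_trees)
        if tree_noise_sd > 0
        else np.ones(n_trees)
    )

    hours = np.arange(24)
    # daylight-weighted diurnal profile, normalised to sum to 1
    prof = np.clip(np.sin(np.pi * (hours - 6) / 12.0), 0.0, None)
    prof = prof / prof.sum()

    recs = []
    for d, date in enumerate(series.index):
        vol_per_m2 = stand_et[d] / CM3_PER_M2_TO_MM  # cm3/day per m2 crown
        for j in range(n_trees):
            daily_vol = vol_per_m2 * ac[j] * tree_factor[j]
            for h in hours:
                recs.append(
                    (date, f"tree{j:03d}", species[j], ab[j], daily_vol * prof[h])
                )
    table = pd.DataFrame(recs, columns=["date", "tree_id", "species", "A_b", "sapflow_cm3h"])
    return table, series


def make_training_world(
    n_rows: int = 50_000,
    n_sites: int = 20,
    noise_sd_mm: float = 0.05,
    seed: int = 0,
    truth: TruthStressSpec | None = None,
    veg_class: str = "tall",
    ept_scaling: str = "none",
) -> pd.DataFrame:
    """The default multi-site training world: ``n_rows`` site-days spread
    over ``n_sites`` sites with distinct climates, observations carrying
    Gaussian noise of ``noise_sd_mm`` on E, and the training-table pipeline
    applied per site (rain days removed, stress targets formed).

    Returns the pooled training table with the ground-truth stress kept in
    ``S_t_true`` for recovery experiments. Because the world's potential
    transpiration is exact (no grid-scale mismatch), the default scaling
    mode is ``"none"``; pass ``"post_rain"`` to exercise the bias
    correction.
    """
    from .prep import build_training_table

    rng = np.random.default_rng(seed)
    truth_base = truth or TruthStressSpec(noise_sd_mm=noise_sd_mm)
    truth_spec = TruthStressSpec(**{**truth_base.__dict__, "noise_sd_mm": noise_sd_mm})
    n_days = max(int(np.ceil(n_rows / n_sites)), 730)  # anomalies need full years
    soil = SoilParams.tall() if veg_class == "tall" else SoilParams.short()

    tables = []
    for s in range(n_sites):
        climate = ClimateParams(
            mat_C=float(rng.uniform(4, 20)),
            swi_mean_wm2=float(rng.uniform(140, 220)),
            wet_prob_after_dry=float(rng.uniform(0.08, 0.28)),
            mean_rain_mm=float(rng.uniform(3, 9)),
            vod_mean=float(rng.uniform(0.4, 0.75)),
        )
        site_seed = int(rng.integers(0, 2**31 - 1))
        forcing = generate_forcing(site_seed, n_days, climate)
        series = generate_observations(forcing, truth_spec, soil, seed=site_seed + 1, climate=climate)
        tab = build_training_table(
            series.rename(columns={"E_obs": "E_t"}),
            veg_class=veg_class,
            ept_scaling=ept_scaling,
            already_transpiration=True,
        )
        tab["S_t_true"] = series.loc[tab.index, "S_t_true"]
        tab["site_id"] = f"SYN-{s:03d}"
        tables.append(tab)
    return pd.concat(tables, axis=0)


def generate_grid_world(
    seed: int,
    n_days: int,
    ny: int = 2,
    nx: int = 2,
    climate: ClimateParams = ClimateParams(),
):
    """A toy gridded forcing world as an xarray Dataset (time, y, x), one
    variable per driver with units metadata; cells differ by seed."""
    import xarray as xr

    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(ny * nx):
        cell_seed = int(rng.integers(0, 2**31 - 1))
        cells.append(generate_forcing(cell_seed, n_days, climate))
    time = cells[0].index
    units = {"P": "mm/day", "Rn": "W/m2", "Ta": "degC", "VPD": "kPa",
             "SWi": "W/m2", "VOD": "1", "CO2": "ppm", "LAI": "m2/m2"}
    data = {}
    for var in cells[0].columns:
        arr = np.stack([c[var].to_numpy() for c in cells]).reshape(ny, nx, len(time))
        data[var] = xr.DataArray(
            np.moveaxis(arr, 2, 0),
            dims=("time", "y", "x"),
            coords={"time": time, "y": np.arange(ny), "x": np.arange(nx)},
            attrs={"units": units.get(var, "")},
        )
    return xr.Dataset(data)


def write_site_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Site table to CSV with the date as first column."""
    df.to_csv(path, index_label="date")


def write_grid_netcdf(ds, path: str | Path) -> None:
    """Gridded world to a NetCDF3 file (scipy backend)."""
    ds.to_netcdf(path, engine="scipy")
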