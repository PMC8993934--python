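"""Supervised training-table construction for the learned stress model.

The target is the tower-scale transpiration stress::

    S_t = E_t / E_pt_scaled, clamped to [0, 1]

where E_t is transpiration partitioned from observed evaporation with a
LAI-based ratio (or upscaled from per-tree sap flow) and E_pt_scaled is
bias-corrected potential transpiration. Rain days are removed before any
target is formed, so interception loss and wet-sensor errors do not
contaminate the stress estimates, and days with near-zero potential
transpiration are dropped (the ratio is unstable there).

Covariates are the absolute values and seasonal anomalies of six drivers:
plant available water (PAW), vapour pressure deficit (VPD), air temperature
(Ta), incoming shortwave radiation (SWi), vegetation optical depth (VOD) and
atmospheric CO2 — 12 features in the fixed order of :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pet import DEFAULT_RAIN_THRESHOLD_MM, post_rain_mask, rain_day_mask, scale_ept

__all__ = [
    "COVARIATES",
    "FEATURE_NAMES",
    "partition_et",
    "filter_rain_days",
    "stress_target",
    "crown_area",
    "upscale_sapflow",
    "seasonal_anomaly",
    "build_feature_frame",
    "build_training_table",
    "CROWN_AREA_COEFS",
]

#: Driver names, in canonical order.
COVARIATES = ("PAW", "VPD", "Ta", "SWi", "VOD", "CO2")
#: The 12 network features: absolutes first, then seasonal anomalies.
FEATURE_NAMES = tuple(c for c in COVARIATES) + tuple(f"{c}_anom" for c in COVARIATES)

#: Crown-area allometry: ln A_c = a0 + a1*ln A_b + a2*MAT + a3*MAP
#: (natural logs, A_b and A_c in m2, MAT degC, MAP mm/yr).
CROWN_AREA_COEFS = (-2.53, 6.02e-01, 9.60e-02, -5.48e-05)

#: Per-tree sap-flow volume per unit crown area, cm3/day per m2, to mm/day.
CM3_PER_M2_TO_MM = 1e-3

DEFAULT_EPT_EPSILON_MM = 0.1
DEFAULT_PARTITION_K = {"tall": 0.6, "short": 0.8}


def partition_et(E_obs, LAI, veg_class: str = "tall", k: float | None = None):
    """Transpiration partitioned from total evaporation via a LAI ratio.

    The transpiration fraction is a monotone saturating function of leaf
    area, ``r = 1 - exp(-k * LAI)``: leafless ground transpires nothing and
    dense canopies route nearly all the flux through stomata. ``k`` defaults
    per vegetation class (:data:`DEFAULT_PARTITION_K`) and is configurable —
    any monotone ratio model can stand in.
    """
    E = np.asarray(E_obs, dtype=float)
    lai = np.asarray(LAI, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    if np.any(E < 0):
        raise ValueError("observed evaporation must be non-negative")
    if k is None:
        k = DEFAULT_PARTITION_K[veg_class]
    et = E * (1.0 - np.exp(-k * lai))
    if np.isscalar(E_obs) and np.isscalar(LAI):
        return float(et)
    return et


def filter_rain_days(
    df: pd.DataFrame,
    rain_threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM,
    p_col: str = "P",
) -> tuple[pd.DataFrame, dict]:
    """Drop rows with precipitation above the threshold.

    Returns the retained frame and counts ``{"retained": n, "removed": m}``.
    """
    wet = rain_day_mask(df[p_col].to_numpy(), rain_threshold_mm)
    retained = df.loc[~wet].copy()
    return retained, {"retained": int((~wet).sum()), "removed": int(wet.sum())}


def stress_target(
    E_t,
    E_pt_scaled,
    epsilon_mm: float = DEFAULT_EPT_EPSILON_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Stress targets S_t = E_t / E_pt_scaled clamped to [0, 1].

    Days with potential transpiration at or below ``epsilon_mm`` are invalid
    (the ratio is numerically unstable near zero) and come back masked.

    Returns
    -------
    (targets, valid) : arrays
        ``targets`` is NaN where ``valid`` is False.
    """
    et = np.asarray(E_t, dtype=float)
    ept = np.asarray(E_pt_scaled, dtype=float)
    valid = ept > epsilon_mm
    st = np.full_like(et, np.nan)
    st[valid] = np.clip(et[valid] / ept[valid], 0.0, 1.0)
    return st, valid


def crown_area(A_b, MAT, MAP) -> float | np.ndarray:
    """Projected crown area (m2) from trunk basal area, site mean annual
    temperature (degC) and precipitation (mm/yr), via the allometry
    ``ln A_c = -2.53 + 0.602 ln A_b + 0.0960 MAT - 5.48e-5 MAP``."""
    ab = np.asarray(A_b, dtype=float)
    if np.any(ab <= 0):
        raise ValueError("basal area must be positive")
    a0, a1, a2, a3 = CROWN_AREA_COEFS
    ac = np.exp(a0 + a1 * np.log(ab) + a2 * np.asarray(MAT, float) + a3 * np.asarray(MAP, float))
    if np.isscalar(A_b):
        return float(ac)
    return ac


def upscale_sapflow(table: pd.DataFrame, site_mat: float, site_map: float) -> pd.Series:
    """Stand transpiration (mm/day) from a per-tree sub-daily sap-flow table.

    Expected columns: ``date``, ``tree_id``, ``species``, ``A_b`` (basal
    area, m2), ``sapflow_cm3h`` (volume flow). Steps: sum each tree's flow to
    a daily volume, divide by its allometric crown area, average trees within
    a species, then weight species means by the stand's basal-area
    composition. 1 cm3/day over 1 m2 of crown is 1e-3 mm/day.

    Rows without a basal area are dropped with a warning.
    """
    import warnings

    if len(table) == 0:
        raise ValueError("sap-flow table is empty")
    tab = table.copy()
    missing = tab["A_b"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} rows with missing basal area", stacklevel=2)
        tab = tab.loc[~missing]
    if len(tab) == 0:
        raise ValueError("no sap-flow rows with basal area")

    # per-tree daily volume and flow per unit crown area
    per_tree = (
        tab.groupby(["date", "tree_id"])
        .agg(vol_cm3=("sapflow_cm3h", "sum"), species=("species", "first"), A_b=("A_b", "first"))
        .reset_index()
    )
    per_tree["A_c"] = crown_area(per_tree["A_b"].to_numpy(), site_mat, site_map)
    per_tree["flow_mm"] = per_tree["vol_cm3"] / per_tree["A_c"] * CM3_PER_M2_TO_MM

    # species means, weighted by basal-area composition of the stand
    trees = per_tree.drop_duplicates("tree_id")[["tree_id", "species", "A_b"]]
    ba_by_species = trees.groupby("species")["A_b"].sum()
    weights = ba_by_species / ba_by_species.sum()

    sp_daily = per_tree.groupby(["date", "species"])["flow_mm"].mean().unstack("species")
    stand = (sp_daily * weights).sum(axis=1, min_count=1)
    stand.name = "E_t_mm"
    return stand


def doy_climatology(series: pd.Series, window_days: int = 31) -> pd.Series:
    """Smoothed day-of-year climatology of a daily series.

    Mean per day of year over all available years, smoothed with a centred
    circular moving average of ``window_days``; day 366 is folded into day
    365. Returns a Series indexed 1..365. Needs >= 1 full year of data.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    if len(series) < 365:
        raise ValueError("climatology needs at least one full year of data")
    doy = series.index.dayofyear.to_numpy()
    clim = series.groupby(doy).mean()
    if 366 in clim.index:
        n366 = (doy == 366).sum()
        n365 = (doy == 365).sum()
        if 365 in clim.index:
            clim.loc[365] = (clim.loc[365] * n365 + clim.loc[366] * n366) / (n365 + n366)
        else:
            clim.loc[365] = clim.loc[366]
        clim = clim.drop(366)
    full = clim.reindex(range(1, 366)).interpolate(limit_direction="both")
    vals = full.to_numpy()
    half = window_days // 2
    padded = np.concatenate([vals[-half:], vals, vals[:half]])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return pd.Series(smoothed, index=full.index)


def seasonal_anomaly(
    series: pd.Series,
    window_days: int = 31,
) -> pd.Series:
    """Departure from the smoothed day-of-year climatology
    (:func:`doy_climatology`). Anomalies of a constant series are zero."""
    clim_smooth = doy_climatology(series, window_days)
    doy_clamped = np.minimum(series.index.dayofyear.to_numpy(), 365)
    return series - clim_smooth.loc[doy_clamped].to_numpy()


def build_feature_frame(drivers: pd.DataFrame, window_days: int = 31) -> pd.DataFrame:
    """Assemble the 12-column feature frame (absolutes + seasonal anomalies)
    from a daily driver frame with a DatetimeIndex and the six
    :data:`COVARIATES` columns."""
    missing = [c for c in COVARIATES if c not in drivers.columns]
    if missing:
        raise ValueError(f"driver frame missing columns: {missing}")
    out = pd.DataFrame(index=drivers.index)
    for c in COVARIATES:
        out[c] = drivers[c].astype(float)
    for c in COVARIATES:
        out[f"{c}_anom"] = seasonal_anomaly(drivers[c].astype(float), window_days)
    return out[list(FEATURE_NAMES)]


def build_training_table(
    site_df: pd.DataFrame,
    veg_class: str = "tall",
    rain_threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM,
    ept_scaling: str = "post_rain",
    partition_k: float | None = None,
    ept_epsilon_mm: float = DEFAULT_EPT_EPSILON_MM,
    anomaly_window_days: int = 31,
    already_transpiration: bool = False,
) -> pd.DataFrame:
    """Build the covariate + target table for one site.

    ``site_df`` must carry a DatetimeIndex, the six driver columns, ``P``,
    ``LAI``, ``E_obs`` (or ``E_t`` when ``already_transpiration``, e.g. from
    sap flow) and ``E_pt_raw``.

    ``ept_scaling`` selects the bias-correction moments: ``"post_rain"``
    (days following rain days — the default), ``"full"`` (all retained days)
    or ``"none"`` (use the raw series unchanged).
    """
    features = build_feature_frame(site_df, anomaly_window_days)
    P = site_df["P"].to_numpy(dtype=float)
    if already_transpiration:
        et = site_df["E_t"].to_numpy(dtype=float)
    else:
        et = partition_et(site_df["E_obs"].to_numpy(dtype=float),
                          site_df["LAI"].to_numpy(dtype=float), veg_class, k=partition_k)
    ept_raw = site_df["E_pt_raw"].to_numpy(dtype=float)

    wet = rain_day_mask(P, rain_threshold_mm)
    post = post_rain_mask(P, rain_threshold_mm)

    if ept_scaling == "none":
        ept_scaled = ept_raw
    elif ept_scaling == "post_rain":
        ept_scaled = scale_ept(ept_raw, et, post)
    elif ept_scaling == "full":
        ept_scaled = scale_ept(ept_raw, et, ~wet)
    else:
        raise ValueError(f"unknown ept_scaling mode {ept_scaling!r}")

    st, valid = stress_target(et, ept_scaled, ept_epsilon_mm)

    out = features.copy()
    out["E_t"] = et
    out["E_pt_raw"] = ept_raw
    out["E_pt_scaled"] = ept_scaled
    out["rain_day"] = wet
    out["post_rain"] = post
    out["S_t_target"] = st
    out["veg_class"] = veg_class
    keep = ~wet & valid & out[list(FEATURE_NAMES)].notna().all(axis=1).to_numpy()
    return out.loc[keep]
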