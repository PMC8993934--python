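"""Priestley-Taylor potential evaporation, simple interception and the
site-level bias correction of potential transpiration.

The Priestley-Taylor (PT) formulation gives daily potential evaporation from
net radiation and air temperature alone::

    E_p = alpha * Delta / (Delta + gamma) * Rn / lambda_v

with Delta the slope of the saturation vapour pressure curve (FAO-56 closed
form), gamma the psychrometric constant and lambda_v the latent heat of
vaporization. Ground heat flux is neglected at the daily scale and alpha
defaults to the classical 1.26.

The bias correction rescales a raw potential-transpiration series to the
moments of observed transpiration on days following rain days, under the
assumption that ecosystems transpire at their potential right after rainfall.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "priestley_taylor",
    "scale_ept",
    "interception_simple",
    "rain_day_mask",
    "post_rain_mask",
    "ALPHA_PT",
    "GAMMA_KPA_PER_C",
    "LAMBDA_MJ_PER_KG",
]

ALPHA_PT = 1.26
GAMMA_KPA_PER_C = 0.0665  # psychrometric constant at sea level, kPa/degC
LAMBDA_MJ_PER_KG = 2.45  # latent heat of vaporization, MJ/kg
W_M2_TO_MJ_M2_DAY = 0.0864
DEFAULT_RAIN_THRESHOLD_MM = 0.5


def svp_slope(Ta_C):
    """Slope of the saturation vapour pressure curve, kPa/degC (FAO-56)."""
    Ta = np.asarray(Ta_C, dtype=float)
    es = 0.6108 * np.exp(17.27 * Ta / (Ta + 237.3))
    return 4098.0 * es / (Ta + 237.3) ** 2


def priestley_taylor(Rn_wm2, Ta_C, alpha: float = ALPHA_PT, gamma: float = GAMMA_KPA_PER_C):
    """Daily Priestley-Taylor potential evaporation in mm/day.

    Parameters
    ----------
    Rn_wm2 : array_like
        Net radiation, W/m2. Negative values floor E_p at zero.
    Ta_C : array_like
        Air temperature, degC, within (-60, 60).
    alpha : float
        Priestley-Taylor coefficient (default 1.26).
    """
    Ta = np.asarray(Ta_C, dtype=float)
    if np.any(Ta <= -60) or np.any(Ta >= 60):
        raise ValueError("air temperature outside physical range (-60, 60) degC")
    Rn = np.asarray(Rn_wm2, dtype=float)
    delta = svp_slope(Ta)
    rn_mj = np.maximum(Rn, 0.0) * W_M2_TO_MJ_M2_DAY
    ep = alpha * delta / (delta + gamma) * rn_mj / LAMBDA_MJ_PER_KG
    ep = np.maximum(ep, 0.0)
    if np.isscalar(Rn_wm2) and np.isscalar(Ta_C):
        return float(ep)
    return ep


def rain_day_mask(P_mm, threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM) -> np.ndarray:
    """Boolean mask of rain days: precipitation above the threshold."""
    return np.asarray(P_mm, dtype=float) > threshold_mm


def post_rain_mask(P_mm, threshold_mm: float = DEFAULT_RAIN_THRESHOLD_MM) -> np.ndarray:
    """Days following rain days: a dry day immediately preceded by >=1 rain day."""
    rain = rain_day_mask(P_mm, threshold_mm)
    post = np.zeros_like(rain)
    post[1:] = rain[:-1] & ~rain[1:]
    return post


def scale_ept(
    ept_raw,
    et_flux,
    subset_mask,
    ddof: int = 1,
) -> np.ndarray:
    """Rescale raw potential transpiration to observed-transpiration moments.

    The affine map standardises ``ept_raw`` with its own mean/sd on the
    ``subset_mask`` days (the days following rain days) and maps it onto the
    mean/sd of ``et_flux`` on the same days; the map is then applied to the
    full series. Sample standard deviation (ddof=1) by default.

    Raises
    ------
    ValueError
        If the subset has fewer than two days or zero raw variance.
    """
    ept_raw = np.asarray(ept_raw, dtype=float)
    et_flux = np.asarray(et_flux, dtype=float)
    mask = np.asarray(subset_mask, dtype=bool)
    if ept_raw.shape != et_flux.shape or ept_raw.shape != mask.shape:
        raise ValueError("series and mask must share a shape")
    if mask.sum() < 2:
        raise ValueError("post-rain subset needs at least two days")
    raw_sub = ept_raw[mask]
    flux_sub = et_flux[mask]
    mean_raw, sd_raw = raw_sub.mean(), raw_sub.std(ddof=ddof)
    if sd_raw == 0:
        raise ValueError("raw potential transpiration has zero variance on the subset")
    mean_flux, sd_flux = flux_sub.mean(), flux_sub.std(ddof=ddof)
    return (ept_raw - mean_raw) / sd_raw * sd_flux + mean_flux


def interception_simple(P_mm, LAI, coef: float = 0.2):
    """Interception loss as the rain amount retained by the canopy,
    capped by a LAI-proportional storage: ``E_i = min(P, coef * LAI)``.

    A deliberate simplification of analytical interception models; ``coef``
    (mm per unit LAI) is the daily canopy storage capacity.
    """
    P = np.asarray(P_mm, dtype=float)
    if np.any(P < 0):
        raise ValueError("precipitation must be non-negative")
    lai = np.asarray(LAI, dtype=float)
    ei = np.minimum(P, coef * lai)
    ei = np.maximum(ei, 0.0)
    if np.isscalar(P_mm) and np.isscalar(LAI):
        return float(ei)
    return ei
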