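"""Process-based evaporative stress formulations.

The transpiration stress factor couples vegetation water content (microwave
vegetation optical depth, VOD) with root-zone water availability::

    S_t = sqrt(VOD / VOD_max) * (1 - ((w_c - w_w) / (w_c - w_wp))**2)

where VOD_max is the 99th-percentile VOD of the site record, w_w the moisture
of the wettest soil layer, w_c critical moisture and w_wp wilting point.
Inputs are clamped (VOD <= VOD_max, w_wp <= w_w <= w_c) so the factor stays in
[0, 1]; the raw expression is negative below wilting point and exceeds one
above critical moisture, neither of which is physically meaningful for a
multiplicative stress.

Bare-soil stress is linear in surface moisture::

    S_b = 1 - (w_c - w_1) / (w_c - w_r)

clamped to [0, 1], with w_r the residual moisture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soil import SoilParams

__all__ = ["StressParams", "process_st", "process_sb", "compute_vodmax", "ProcessStressModel"]


@dataclass(frozen=True)
class StressParams:
    """Parameters of the process stress functions."""

    vod_max: float
    soil: SoilParams

    def __post_init__(self) -> None:
        if self.vod_max <= 0:
            raise ValueError("VOD_max must be positive")


def process_st(VOD, w_w, params: StressParams):
    """Process-based transpiration stress in [0, 1]."""
    soil = params.soil
    denom = soil.w_c - soil.w_wp
    if denom <= 0:
        raise ValueError("w_c must exceed w_wp")
    vod = np.clip(np.asarray(VOD, dtype=float), 0.0, params.vod_max)
    ww = np.clip(np.asarray(w_w, dtype=float), soil.w_wp, soil.w_c)
    st = np.sqrt(vod / params.vod_max) * (1.0 - ((soil.w_c - ww) / denom) ** 2)
    st = np.clip(st, 0.0, 1.0)
    if np.isscalar(VOD) and np.isscalar(w_w):
        return float(st)
    return st


def process_sb(w_1, params: SoilParams):
    """Bare-soil evaporative stress in [0, 1]."""
    denom = params.w_c - params.w_r
    if denom <= 0:
        raise ValueError("w_c must exceed w_r")
    sb = 1.0 - (params.w_c - np.asarray(w_1, dtype=float)) / denom
    sb = np.clip(sb, 0.0, 1.0)
    if np.isscalar(w_1):
        return float(sb)
    return sb


def compute_vodmax(vod_series, q: float = 99.0) -> float:
    """99th percentile of a VOD record, linear-interpolation convention
    (numpy's default ``linear`` method)."""
    vod = np.asarray(vod_series, dtype=float)
    if vod.size == 0:
        raise ValueError("VOD series is empty")
    return float(np.percentile(vod, q))


class ProcessStressModel:
    """Process stress packaged behind the same predictor interface the
    learned model exposes, so the coupler can swap them freely.

    The coupler hands every predictor a dict of named covariates; this one
    reads only ``VOD`` and ``w_w``.
    """

    def __init__(self, params: StressParams):
        self.params = params

    def predict_stress(self, covariates: dict) -> float:
        return process_st(covariates["VOD"], covariates["w_w"], self.params)
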