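"""Multi-layer soil water balance.

A tipping-bucket column: rainfall infiltrates into the top layer, moisture in
excess of porosity cascades downwards, excess leaving the bottom layer drains
out of the column. Transpiration is extracted from the wettest layer and
bare-soil evaporation from the surface layer; extraction is capped so no layer
is drawn below residual moisture. Tall vegetation uses a three-layer column,
short vegetation (and bare soil) a two-layer column.

Plant available water (PAW) scales the wettest-layer moisture between wilting
point ``w_wp`` and critical moisture ``w_c``::

    PAW = (w_w - w_wp) / (w_c - w_wp)

and is clamped to [0, 1]: moisture above ``w_c`` means no water limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SoilParams",
    "SoilState",
    "StepResult",
    "compute_paw",
    "step_water_balance",
    "initial_state",
    "TALL_DEPTHS_MM",
    "SHORT_DEPTHS_MM",
]

#: Default layer depths (mm). Placeholders in the spirit of a three-layer
#: (tall) / two-layer (short) column; not calibrated values.
TALL_DEPTHS_MM = (100.0, 400.0, 800.0)
SHORT_DEPTHS_MM = (100.0, 400.0)


@dataclass(frozen=True)
class SoilParams:
    """Hydraulic parameters of a soil column.

    All moistures are volumetric (m3/m3) and must satisfy
    ``w_r < w_wp < w_c < porosity``.
    """

    depths_mm: tuple[float, ...] = TALL_DEPTHS_MM
    w_wp: float = 0.10
    w_c: float = 0.30
    w_r: float = 0.05
    porosity: float = 0.45

    def __post_init__(self) -> None:
        if not (self.w_r < self.w_wp < self.w_c < self.porosity):
            raise ValueError(
                "soil parameters must satisfy w_r < w_wp < w_c < porosity, got "
                f"w_r={self.w_r}, w_wp={self.w_wp}, w_c={self.w_c}, "
                f"porosity={self.porosity}"
            )
        if len(self.depths_mm) < 1 or any(d <= 0 for d in self.depths_mm):
            raise ValueError("layer depths must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.depths_mm)

    @classmethod
    def tall(cls, **kw) -> "SoilParams":
        return cls(depths_mm=TALL_DEPTHS_MM, **kw)

    @classmethod
    def short(cls, **kw) -> "SoilParams":
        return cls(depths_mm=SHORT_DEPTHS_MM, **kw)


@dataclass
class SoilState:
    """Per-layer volumetric moisture plus the derived quantities the stress
    formulations read: surface moisture ``w_1``, wettest-layer moisture
    ``w_w`` and plant available water ``PAW``."""

    w: np.ndarray  # volumetric moisture per layer

    @property
    def w_1(self) -> float:
        return float(self.w[0])

    @property
    def w_w(self) -> float:
        return float(np.max(self.w))

    def paw(self, params: SoilParams) -> float:
        return compute_paw(self.w_w, params)

    def storage_mm(self, params: SoilParams) -> float:
        """Total column water storage in mm."""
        return float(np.dot(self.w, np.asarray(params.depths_mm)))

    def validate(self, params: SoilParams, atol: float = 1e-9) -> None:
        if len(self.w) != params.n_layers:
            raise ValueError("state/parameter layer count mismatch")
        if np.any(self.w < params.w_r - atol) or np.any(self.w > params.porosity + atol):
            raise ValueError("layer moisture outside [w_r, porosity]")


@dataclass
class StepResult:
    """Outcome of one daily water-balance step."""

    state: SoilState
    drainage_mm: float  # water leaving the bottom of the column
    e_t_actual_mm: float  # transpiration actually extracted
    e_b_actual_mm: float  # bare-soil evaporation actually extracted
    shortfall_mm: float  # requested minus actual extraction

    @property
    def e_actual_mm(self) -> float:
        return self.e_t_actual_mm + self.e_b_actual_mm


def compute_paw(w_w: float, params: SoilParams) -> float:
    """Plant available water from the wettest-layer moisture, clamped to [0, 1]."""
    denom = params.w_c - params.w_wp
    if denom <= 0:
        raise ValueError("w_c must exceed w_wp")
    return float(np.clip((w_w - params.w_wp) / denom, 0.0, 1.0))


def initial_state(params: SoilParams, w0: float | None = None) -> SoilState:
    """Column initialised at a uniform moisture (default: critical moisture)."""
    w0 = params.w_c if w0 is None else w0
    w0 = float(np.clip(w0, params.w_r, params.porosity))
    return SoilState(w=np.full(params.n_layers, w0, dtype=float))


def step_water_balance(
    state: SoilState,
    P_mm: float,
    e_t_mm: float,
    e_b_mm: float,
    params: SoilParams,
) -> StepResult:
    """Advance the column by one day.

    Order of operations: infiltrate ``P_mm`` into the top layer, cascade any
    moisture above porosity downwards (the bottom layer's excess drains out),
    then extract bare-soil evaporation ``e_b_mm`` from the surface layer and
    transpiration ``e_t_mm`` from the wettest layer. Extraction never draws a
    layer below ``w_r``; any shortfall is reported, not silently absorbed.

    Mass balance holds to machine precision:
    ``P - E_actual - drainage == storage_after - storage_before``.
    """
    state.validate(params)
    if P_mm < 0:
        raise ValueError("precipitation must be non-negative")
    if e_t_mm < 0 or e_b_mm < 0:
        raise ValueError("extraction demands must be non-negative")

    depths = np.asarray(params.depths_mm)
    w = state.w.astype(float).copy()

    # infiltration
    w[0] += P_mm / depths[0]

    # cascade drainage of super-porosity water
    drainage = 0.0
    for i in range(params.n_layers):
        excess = max(w[i] - params.porosity, 0.0)
        if excess > 0:
            w[i] = params.porosity
            excess_mm = excess * depths[i]
            if i + 1 < params.n_layers:
                w[i + 1] += excess_mm / depths[i + 1]
            else:
                drainage += excess_mm

    # extraction, capped at water available above residual moisture
    avail_b = (w[0] - params.w_r) * depths[0]
    e_b_act = min(e_b_mm, max(avail_b, 0.0))
    w[0] -= e_b_act / depths[0]

    i_wet = int(np.argmax(w))
    avail_t = (w[i_wet] - params.w_r) * depths[i_wet]
    e_t_act = min(e_t_mm, max(avail_t, 0.0))
    w[i_wet] -= e_t_act / depths[i_wet]

    shortfall = (e_t_mm - e_t_act) + (e_b_mm - e_b_act)
    # guard against negative zero / rounding at the residual floor
    w = np.maximum(w, params.w_r)
    return StepResult(
        state=SoilState(w=w),
        drainage_mm=drainage,
        e_t_actual_mm=e_t_act,
        e_b_actual_mm=e_b_act,
        shortfall_mm=shortfall,
    )
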