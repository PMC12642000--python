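"""Core parameter containers for the minimal PBPK model.

The model lumps the body into plasma, tight tissue (muscle, skin, adipose,
brain), leaky tissue (liver, kidney, heart and other highly vascularised
organs) and lymph.  Antibody enters the interstitium by convective lymph
filtration, returns via lymph, and is eliminated from plasma only.

Canonical internal units are grams, litres and days.  Anti-D quantities
(micrograms, ng/mL) are converted at the I/O boundary: 1 ng/mL = 1e-6 g/L.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Route",
    "PhysiologyParams",
    "DrugParams",
    "DoseEvent",
    "ConcentrationProfile",
    "NG_PER_ML_TO_G_PER_L",
    "UG_TO_G",
]

NG_PER_ML_TO_G_PER_L = 1e-6
UG_TO_G = 1e-6


class Route(str, enum.Enum):
    """Administration route of a dose event."""

    IV_INFUSION = "iv_infusion"
    IM = "im"


class PhysiologyParams(BaseModel):
    """Physiological state of one subject.

    Parameters
    ----------
    plasma_volume, tight_volume, leaky_volume, lymph_volume
        Compartment volumes in litres.
    lymph_flow_total
        Total lymph flow L (L/day).  The flow splits into a tight-tissue
        branch ``L1 = (1 - leaky_flow_fraction) * L`` and a leaky-tissue
        branch ``L2 = leaky_flow_fraction * L``.
    sigma_lymph
        Lymphatic capillary reflection coefficient (dimensionless, [0, 1)).
    leaky_flow_fraction
        Fraction of lymph flow perfusing the leaky tissues (default 2/3 in
        the two-tissue minimal PBPK framework).
    bodyweight
        Subject bodyweight in kg.
    trimester
        0 for nonpregnant, 1-3 for pregnancy trimesters.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    plasma_volume: float
    tight_volume: float
    leaky_volume: float
    lymph_volume: float
    lymph_flow_total: float
    sigma_lymph: float = 0.2
    leaky_flow_fraction: float = 2.0 / 3.0
    bodyweight: float = 70.0
    trimester: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhysiologyParams":
        for name in ("plasma_volume", "tight_volume", "leaky_volume", "lymph_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lymph_flow_total <= 0:
            raise ValueError("lymph_flow_total must be > 0")
        if not 0.0 <= self.sigma_lymph < 1.0:
            raise ValueError("sigma_lymph must be in [0, 1)")
        if not 0.0 < self.leaky_flow_fraction < 1.0:
            raise ValueError("leaky_flow_fraction must be in (0, 1)")
        if self.bodyweight <= 0:
            raise ValueError("bodyweight must be > 0")
        if self.trimester not in (0, 1, 2, 3):
            raise ValueError("trimester must be in {0, 1, 2, 3}")
        return self

    @property
    def lymph_flow_tight(self) -> float:
        """L1: lymph flow through tight tissues (L/day)."""
        return (1.0 - self.leaky_flow_fraction) * self.lymph_flow_total

    @property
    def lymph_flow_leaky(self) -> float:
        """L2: lymph flow through leaky tissues (L/day)."""
        return self.leaky_flow_fraction * self.lymph_flow_total


class DrugParams(BaseModel):
    """Analyte-specific parameters.

    ``sigma_tight`` / ``sigma_leaky`` are the vascular reflection
    coefficients of the tight and leaky tissues (sigma_tight >=
    sigma_leaky: tight tissue is less permeable).  ``baseline_conc`` is the
    endogenous plasma concentration of the analyte (g/L); zero for anti-D
    Ig in non-sensitised women.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    clearance: float
    sigma_tight: float = 0.97
    sigma_leaky: float = 0.94
    ka: float | None = None
    bioavailability_im: float = 1.0
    baseline_conc: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "DrugParams":
        if self.clearance <= 0:
            raise ValueError("clearance must be > 0")
        if not 0.0 <= self.sigma_tight <= 1.0:
            raise ValueError("sigma_tight must be in [0, 1]")
        if not 0.0 <= self.sigma_leaky <= 1.0:
            raise ValueError("sigma_leaky must be in [0, 1]")
        if self.sigma_tight < self.sigma_leaky:
            raise ValueError("sigma_tight must be >= sigma_leaky")
        if self.ka is not None and self.ka <= 0:
            raise ValueError("ka must be > 0 when given")
        if not 0.0 < self.bioavailability_im <= 1.0:
            raise ValueError("bioavailability_im must be in (0, 1]")
        if self.baseline_conc < 0:
            raise ValueError("baseline_conc must be >= 0")
        return self


class DoseEvent(BaseModel):
    """One administration: an IV infusion or an IM depot dose.

    ``amount`` is in grams; ``start_time`` and ``infusion_duration`` in
    days.  ``infusion_duration`` applies to IV infusions only.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    route: Route
    amount: float
    start_time: float = 0.0
    infusion_duration: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "DoseEvent":
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.route is Route.IV_INFUSION:
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise ValueError("iv_infusion requires infusion_duration > 0")
        return self

    @property
    def end_time(self) -> float:
        if self.route is Route.IV_INFUSION:
            return self.start_time + float(self.infusion_duration)
        return self.start_time


@dataclass
class ConcentrationProfile:
    """Simulated or observed concentration-time course.

    ``plasma``/``tight``/``leaky``/``lymph`` are concentrations (g/L) on
    ``times`` (days); ``depot_amount`` is the mass remaining at an IM
    injection site (g).  ``amounts`` retains the raw solver output (amounts
    per compartment, possibly with tiny negative round-off) for mass-balance
    diagnostics, while the concentration series are clipped at zero.
    """

    times: np.ndarray
    plasma: np.ndarray
    tight: np.ndarray
    leaky: np.ndarray
    lymph: np.ndarray
    depot_amount: np.ndarray
    units: str = "g/L"
    includes_baseline: bool = False
    amounts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("plasma", "tight", "leaky", "lymph", "depot_amount"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            setattr(self, name, arr)
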