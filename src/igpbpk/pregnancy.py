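"""Pregnancy and bodyweight scaling of the reference physiology.

Reference values describe a typical 70-kg adult.  Tissue/lymph volumes and
lymph flow scale linearly with bodyweight (BW/70); clearance scales
allometrically as (BW/70)^0.75; reflection coefficients are unchanged by
pregnancy.  Plasma volume expands with gestation: +7% in the first
trimester (2.78 L), +27% in the second (3.30 L) and +41% in the third
(3.67 L) at the 70-kg reference, each scaled by BW/70 for other
bodyweights.  All BW terms use the subject's current bodyweight (the
pregnant bodyweight after the gestational weight gain is applied).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .params import DrugParams, PhysiologyParams

__all__ = [
    "ReferenceParams",
    "scale_physiology",
    "scale_clearance",
    "pregnant_bodyweight",
    "trimester_baseline",
    "scaled_drug_params",
]

REFERENCE_BODYWEIGHT = 70.0


class ReferenceParams(BaseModel):
    """Reference (70-kg adult) physiology plus pregnancy adjustments."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    reference_bodyweight: float = REFERENCE_BODYWEIGHT
    plasma_volume: float = 2.6
    tight_volume: float = 8.11
    leaky_volume: float = 4.37
    lymph_volume: float = 5.2
    lymph_flow_total: float = 2.9
    sigma_lymph: float = 0.2
    leaky_flow_fraction: float = 2.0 / 3.0
    # trimester -> plasma volume (L) at the 70-kg reference
    trimester_plasma_volume: dict[int, float] = {0: 2.6, 1: 2.78, 2: 3.30, 3: 3.67}
    pregnancy_bw_gain: float = 0.23
    # trimester -> endogenous plasma IgG (g/L); calibrated, not literature-printed
    baseline_igg: dict[int, float] = {0: 13.0, 1: 12.98, 2: 12.95, 3: 12.93}

    @model_validator(mode="after")
    def _check(self) -> "ReferenceParams":
        if self.pregnancy_bw_gain < 0:
            raise ValueError("pregnancy_bw_gain must be >= 0")
        vols = [self.trimester_plasma_volume.get(t) for t in sorted(self.trimester_plasma_volume)]
        if any(v is None or v <= 0 for v in vols):
            raise ValueError("trimester plasma volumes must be positive")
        if any(b < a for a, b in zip(vols[:-1], vols[1:])):
            raise ValueError("trimester_plasma_volume must be non-decreasing in trimester")
        return self


def scale_physiology(
    ref: ReferenceParams, bodyweight: float, trimester: int = 0
) -> PhysiologyParams:
    """Build subject physiology from the 70-kg reference.

    ``bodyweight`` is the subject's current bodyweight (for a pregnant
    subject, after gestational weight gain).  Tissue and lymph volumes and
    lymph flow scale by BW/70; plasma volume uses the trimester-specific
    reference value scaled by BW/70; reflection coefficients are unchanged.
    """
    if bodyweight <= 0:
        raise ValueError("bodyweight must be > 0")
    if trimester not in ref.trimester_plasma_volume:
        raise ValueError(f"unknown trimester {trimester!r}")
    f = bodyweight / ref.reference_bodyweight
    return PhysiologyParams(
        plasma_volume=ref.trimester_plasma_volume[trimester] * f,
        tight_volume=ref.tight_volume * f,
        leaky_volume=ref.leaky_volume * f,
        lymph_volume=ref.lymph_volume * f,
        lymph_flow_total=ref.lymph_flow_total * f,
        sigma_lymph=ref.sigma_lymph,
        leaky_flow_fraction=ref.leaky_flow_fraction,
        bodyweight=bodyweight,
        trimester=trimester,
    )


def scale_clearance(
    ref_clearance: float, bodyweight: float, reference_bodyweight: float = REFERENCE_BODYWEIGHT
) -> float:
    """Allometric clearance: CL_ref * (BW/70)^0.75 (L/day)."""
    if bodyweight <= 0:
        raise ValueError("bodyweight must be > 0")
    return ref_clearance * (bodyweight / reference_bodyweight) ** 0.75


def pregnant_bodyweight(nonpregnant_bw: float, gain_fraction: float = 0.23) -> float:
    """Current bodyweight after gestational weight gain (kg)."""
    if nonpregnant_bw <= 0:
        raise ValueError("nonpregnant_bw must be > 0")
    if gain_fraction < 0:
        raise ValueError("gain_fraction must be >= 0")
    return nonpregnant_bw * (1.0 + gain_fraction)


def trimester_baseline(ref: ReferenceParams, trimester: int, analyte: str) -> float:
    """Endogenous plasma baseline (g/L) for the analyte at a trimester.

    Anti-D Ig has no endogenous counterpart in non-sensitised women, so its
    baseline is always zero.  Total-IgG baselines are configured values
    (calibrated defaults, non-increasing with trimester as hemodilution
    lowers maternal IgG).
    """
    if analyte == "anti_d":
        return 0.0
    if analyte != "ivig":
        raise ValueError(f"unknown analyte {analyte!r}; expected 'ivig' or 'anti_d'")
    try:
        return ref.baseline_igg[trimester]
    except KeyError:
        raise ValueError(f"no baseline IgG configured for trimester {trimester!r}") from None


def scaled_drug_params(
    ref_drug: DrugParams,
    ref: ReferenceParams,
    bodyweight: float,
    trimester: int,
    analyte: str = "ivig",
) -> DrugParams:
    """Drug parameters for one subject: allometric CL + trimester baseline."""
    return ref_drug.model_copy(
        update={
            "clearance": scale_clearance(ref_drug.clearance, bodyweight, ref.reference_bodyweight),
            "baseline_conc": trimester_baseline(ref, trimester, analyte),
        }
    )
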