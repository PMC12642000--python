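"""Synthetic concentration-time datasets and paired-prediction fixtures.

Published immunoglobulin PK profiles exist mostly as digitized figures,
so this module generates literature-like inputs from the model itself:
IVIG plasma IgG profiles (300-600 mg/kg IV, g/L scale, weeks of sampling),
anti-D Ig profiles (300 ug IV or IM, ng/mL scale, third-trimester
subjects) with multiplicative lognormal noise, plus paired
predicted/observed vectors with a prescribed average fold error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import PairedPredictions
from .model import simulate
from .params import (
    NG_PER_ML_TO_G_PER_L,
    UG_TO_G,
    DoseEvent,
    DrugParams,
    Route,
)
from .pregnancy import ReferenceParams, scale_physiology, scaled_drug_params

__all__ = ["SyntheticStudySpec", "generate_study", "generate_paired_predictions"]

DEFAULT_IVIG_TIMES = (0.05, 0.1667, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0)
DEFAULT_ANTI_D_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 56.0)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of one emulated literature study.

    ``dose`` is per-kg (g/kg) for IVIG and absolute grams for anti-D
    (300 ug = 3e-4 g).  ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal observation noise.
    """

    analyte: str = "ivig"  # 'ivig' | 'anti_d'
    route: Route = Route.IV_INFUSION
    dose: float = 0.45  # g/kg for IVIG (450 mg/kg, the average training dose)
    dose_per_kg: bool = True
    bodyweight: float = 70.0
    trimester: int = 0
    sampling_times: tuple[float, ...] = DEFAULT_IVIG_TIMES
    infusion_duration: float = 1.0 / 6.0
    noise_cv: float = 0.0
    include_baseline: bool = True
    seed: int = 0
    subject_id: str = "synthetic-01"

    def __post_init__(self) -> None:
        if self.analyte not in ("ivig", "anti_d"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.sampling_times)
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("sampling_times must be increasing and >= 0")

    @classmethod
    def anti_d_default(cls, route: Route = Route.IM, noise_cv: float = 0.0, seed: int = 0):
        """300 ug anti-D in a third-trimester subject (IV or IM)."""
        return cls(
            analyte="anti_d",
            route=route,
            dose=300.0 * UG_TO_G,
            dose_per_kg=False,
            bodyweight=70.0 * 1.23,
            trimester=3,
            sampling_times=DEFAULT_ANTI_D_TIMES,
            noise_cv=noise_cv,
            include_baseline=False,
            seed=seed,
            subject_id="synthetic-anti-d-01",
        )


def _total_dose(spec: SyntheticStudySpec) -> float:
    return spec.dose * spec.bodyweight if spec.dose_per_kg else spec.dose


def generate_study(
    spec: SyntheticStudySpec,
    ref: ReferenceParams,
    ref_drug: DrugParams,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the true model and add lognormal observation noise.

    Returns the dataset in the tabular observed format together with a
    provenance record (generating parameters and seed) suitable for a
    sidecar file.  With ``noise_cv = 0`` the dataset equals the model
    prediction exactly at the sampling times.
    """
    physio = scale_physiology(ref, spec.bodyweight, spec.trimester)
    drug = scaled_drug_params(ref_drug, ref, spec.bodyweight, spec.trimester, spec.analyte)
    total = _total_dose(spec)
    if spec.route is Route.IV_INFUSION:
        dose_event = DoseEvent(
            route=spec.route, amount=total, start_time=0.0,
            infusion_duration=spec.infusion_duration,
        )
    else:
        dose_event = DoseEvent(route=spec.route, amount=total, start_time=0.0)

    times = np.asarray(spec.sampling_times, dtype=float)
    prof = simulate(
        physio, drug, [dose_event], times,
        superpose_baseline=spec.include_baseline and spec.analyte == "ivig",
    )
    true_conc = prof.plasma

    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        # lognormal with unit mean: E[exp(N(-s^2/2, s^2))] = 1
        s2 = np.log1p(spec.noise_cv**2)
        noise = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=len(times))
        conc = true_conc * noise
    else:
        conc = true_conc.copy()

    if spec.analyte == "anti_d":
        conc_out = conc / NG_PER_ML_TO_G_PER_L
        unit, dose_out, dose_unit = "ng/mL", total / UG_TO_G, "ug"
    else:
        conc_out = conc
        unit, dose_out, dose_unit = "g/L", total, "g"

    data = pd.DataFrame(
        {
            "subject_id": spec.subject_id,
            "time_day": times,
            "conc": conc_out,
            "conc_unit": unit,
            "analyte": spec.analyte,
            "route": spec.route.value,
            "dose": dose_out,
            "dose_unit": dose_unit,
        }
    )
    provenance = {
        "generator": "igpbpk.synthetic.generate_study",
        "seed": spec.seed,
        "noise_cv": spec.noise_cv,
        "analyte": spec.analyte,
        "route": spec.route.value,
        "bodyweight_kg": spec.bodyweight,
        "trimester": spec.trimester,
        "total_dose_g": total,
        "infusion_duration_day": (
            spec.infusion_duration if spec.route is Route.IV_INFUSION else None
        ),
        "include_baseline": bool(spec.include_baseline and spec.analyte == "ivig"),
        "drug_params": drug.model_dump(),
        "physiology": physio.model_dump(),
    }
    return data, provenance


def generate_paired_predictions(
    n: int,
    true_afe: float = 1.17,
    spread: float = 0.1,
    seed: int = 0,
) -> PairedPredictions:
    """Paired predicted/observed vectors with a prescribed AFE.

    Observed values are lognormal around 10 g/L; predicted values carry a
    log10-ratio drawn as N(log10(true_afe), spread^2), so the sample AFE
    converges to ``true_afe`` as n grows.
    """
    if true_afe <= 0:
        raise ValueError("true_afe must be > 0")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    observed = 10.0 * rng.lognormal(mean=0.0, sigma=0.4, size=n)
    log10_ratio = rng.normal(np.log10(true_afe), spread, size=n)
    predicted = observed * 10.0**log10_ratio
    return PairedPredictions(predicted=predicted, observed=observed)
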