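"""Shared fixtures and the independent matrix-exponential oracle.

The oracle builds its own system matrix from the physiological constants
and propagates the piecewise-constant-input linear system with
``scipy.linalg.expm`` (augmented-matrix form, no matrix inversion), so it
shares no code path with the package's ODE integrator.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.linalg import expm

import igpbpk as ig

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def expm_plasma_profile(
    times: np.ndarray,
    *,
    plasma_volume: float,
    tight_volume: float,
    leaky_volume: float,
    lymph_volume: float,
    lymph_flow_total: float,
    sigma_lymph: float,
    leaky_flow_fraction: float,
    sigma_tight: float,
    sigma_leaky: float,
    clearance: float,
    dose_amount: float,
    infusion_duration: float,
    ka: float = 0.0,
    bioavailability_im: float = 1.0,
    im: bool = False,
) -> np.ndarray:
    """Exogenous plasma concentration by matrix exponential (closed form)."""
    L = lymph_flow_total
    L1 = (1.0 - leaky_flow_fraction) * L
    L2 = leaky_flow_fraction * L
    A = np.array(
        [
            [
                -(L1 * (1 - sigma_tight) + L2 * (1 - sigma_leaky) + clearance) / plasma_volume,
                0.0,
                0.0,
                L / lymph_volume,
                ka * bioavailability_im,
            ],
            [L1 * (1 - sigma_tight) / plasma_volume, -L1 * (1 - sigma_lymph) / tight_volume, 0, 0, 0],
            [L2 * (1 - sigma_leaky) / plasma_volume, 0, -L2 * (1 - sigma_lymph) / leaky_volume, 0, 0],
            [
                0.0,
                L1 * (1 - sigma_lymph) / tight_volume,
                L2 * (1 - sigma_lymph) / leaky_volume,
                -L / lymph_volume,
                0.0,
            ],
            [0, 0, 0, 0, -ka],
        ]
    )
    x = np.zeros(5)
    if im:
        x[4] = dose_amount
        segments = [(0.0, float(times[-1]), 0.0)]
    else:
        rate = dose_amount / infusion_duration
        segments = [(0.0, infusion_duration, rate), (infusion_duration, float(times[-1]), 0.0)]
    out = {0.0: x[0]}
    for a, b, rate in segments:
        if b <= a:
            continue
        u = np.zeros(5)
        u[0] = rate
        M = np.zeros((6, 6))
        M[:5, :5] = A
        M[:5, 5] = u
        for t in times[(times > a) & (times <= b)]:
            E = expm(M * (t - a))
            out[float(t)] = (E[:5, :5] @ x + E[:5, 5])[0]
        E = expm(M * (b - a))
        x = E[:5, :5] @ x + E[:5, 5]
    return np.array([out[float(t)] for t in times]) / plasma_volume


REF_70KG = dict(
    plasma_volume=2.6,
    tight_volume=8.11,
    leaky_volume=4.37,
    lymph_volume=5.2,
    lymph_flow_total=2.9,
    sigma_lymph=0.2,
    leaky_flow_fraction=2.0 / 3.0,
    sigma_tight=0.97,
    sigma_leaky=0.94,
    clearance=0.045,
)


@pytest.fixture(scope="session")
def config() -> ig.RunConfig:
    return ig.default_config()


@pytest.fixture(scope="session")
def reference(config) -> ig.ReferenceParams:
    return config.reference()


@pytest.fixture(scope="session")
def physio_70kg(reference) -> ig.PhysiologyParams:
    return ig.scale_physiology(reference, 70.0, 0)


@pytest.fixture(scope="session")
def ivig_drug(config, reference) -> ig.DrugParams:
    """IVIG drug parameters at 70 kg with the calibrated baseline."""
    return ig.scaled_drug_params(
        config.drug_block("ivig").drug_params(), reference, 70.0, 0, "ivig"
    )


@pytest.fixture(scope="session")
def ivig_dose() -> ig.DoseEvent:
    """450 mg/kg x 70 kg, 4-h IV infusion (the training-study average)."""
    return ig.DoseEvent(
        route=ig.Route.IV_INFUSION, amount=0.45 * 70.0, infusion_duration=1.0 / 6.0
    )
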