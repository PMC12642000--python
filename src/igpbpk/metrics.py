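"""Predictive-performance statistics for paired predicted/observed data.

Average fold error (AFE) is the geometric mean of predicted/observed
ratios computed in base 10::

    AFE = 10 ** (mean(log10(pred_i / obs_i)))

A value of 1.0 indicates no prediction error; > 1 indicates systematic
overprediction.  Percent prediction error is the signed relative error in
percent, and fold coverage is the share of pairs whose ratio falls inside
an inclusive fold range (e.g. 0.5-2.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PairedPredictions",
    "afe",
    "percent_prediction_error",
    "fold_coverage",
    "metrics_report",
]


@dataclass
class PairedPredictions:
    """Paired (predicted, observed) concentrations with optional labels."""

    predicted: np.ndarray
    observed: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.predicted.shape != self.observed.shape or self.predicted.ndim != 1:
            raise ValueError("predicted and observed must be 1-D arrays of equal length")
        if len(self.predicted) < 1:
            raise ValueError("at least one pair is required")
        for name, arr in (("predicted", self.predicted), ("observed", self.observed)):
            bad = np.flatnonzero(~(arr > 0))
            if bad.size:
                raise ValueError(
                    f"{name} must be > 0 for every pair (log-ratio undefined); "
                    f"offending pair index {bad[0]}"
                )

    @property
    def ratios(self) -> np.ndarray:
        return self.predicted / self.observed

    def __len__(self) -> int:
        return len(self.predicted)


def afe(pairs: PairedPredictions) -> float:
    """Average fold error: 10 ** mean(log10(pred/obs))."""
    return float(10.0 ** np.mean(np.log10(pairs.ratios)))


def percent_prediction_error(predicted: float, observed: float) -> float:
    """Signed percent prediction error: 100 * (pred - obs) / obs."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(observed <= 0):
        raise ValueError("observed must be > 0")
    out = 100.0 * (predicted - observed) / observed
    return float(out) if out.ndim == 0 else out


def fold_coverage(pairs: PairedPredictions, low: float = 0.5, high: float = 2.0) -> float:
    """Percent of pairs with low <= pred/obs <= high (bounds inclusive)."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    r = pairs.ratios
    return float(100.0 * np.mean((r >= low) & (r <= high)))


def metrics_report(pairs: PairedPredictions) -> dict:
    """AFE plus fold coverage at the two conventional ranges."""
    return {
        "n": len(pairs),
        "afe": afe(pairs),
        "coverage_0.5_2.0": fold_coverage(pairs, 0.5, 2.0),
        "coverage_0.5_1.5": fold_coverage(pairs, 0.5, 1.5),
    }
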