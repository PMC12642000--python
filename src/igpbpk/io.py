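"""Tabular observed-data format and result writers.

Concentration-time data travel as delimiter-separated text with a
mandatory header and the columns::

    subject_id, time_day, conc, conc_unit, analyte, route, dose, dose_unit

Concentrations are g/L for IVIG and ng/mL for anti-D Ig; doses are grams
for IVIG and micrograms for anti-D.  :func:`to_model_units` converts an
observed table to the canonical internal units (g, L, day).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import NG_PER_ML_TO_G_PER_L, UG_TO_G

__all__ = [
    "OBSERVED_COLUMNS",
    "read_observed",
    "write_observed",
    "to_model_units",
    "write_json",
]

OBSERVED_COLUMNS = [
    "subject_id",
    "time_day",
    "conc",
    "conc_unit",
    "analyte",
    "route",
    "dose",
    "dose_unit",
]

_CONC_TO_G_PER_L = {"g/L": 1.0, "ng/mL": NG_PER_ML_TO_G_PER_L}
_DOSE_TO_G = {"g": 1.0, "ug": UG_TO_G, "µg": UG_TO_G}


def read_observed(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read an observed concentration-time table and validate it."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observed data file {path} lacks columns: {missing}")
    if (df["time_day"] < 0).any():
        raise ValueError("times must be >= 0")
    for analyte, grp in df.groupby("analyte"):
        if grp["conc_unit"].nunique() > 1:
            raise ValueError(f"inconsistent concentration units for analyte {analyte!r}")
    return df


def write_observed(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, columns=OBSERVED_COLUMNS)


def to_model_units(df: pd.DataFrame) -> pd.DataFrame:
    """Convert conc to g/L and dose to g; returns a copy with those units."""
    out = df.copy()
    try:
        conc_f = out["conc_unit"].map(_CONC_TO_G_PER_L).astype(float)
        dose_f = out["dose_unit"].map(_DOSE_TO_G).astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unknown unit in observed data: {exc}") from exc
    if conc_f.isna().any() or dose_f.isna().any():
        bad = set(out.loc[conc_f.isna(), "conc_unit"]) | set(out.loc[dose_f.isna(), "dose_unit"])
        raise ValueError(f"unknown units in observed data: {sorted(bad)}")
    out["conc"] = out["conc"] * conc_f
    out["conc_unit"] = "g/L"
    out["dose"] = out["dose"] * dose_f
    out["dose_unit"] = "g"
    return out


def write_json(obj: dict, path: str | Path) -> None:
    """Write a machine-readable result file (numpy-safe JSON)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
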