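"""CSV readers and JSON writers for solubility datasets.

Two input schemas are accepted, both comma-separated UTF-8 with a header:

* gravimetric — ``solvent_id, T_K, m_drug_g, m_solv1_g, m_solv2_g,
  M_drug, M_solv1, M_solv2``; mole fractions and cosolvent fractions are
  computed from the masses.
* direct — ``solvent_id, T_K, w2, x_exp`` with precomputed mole-fraction
  solubility (``w2`` may be omitted or empty for single-solvent data).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import (
    GravimetricRecord,
    cosolvent_fraction,
    mole_fraction_ternary,
)
from .exceptions import InvalidInputError
from .models import MixtureGrid, TemperatureSeries

__all__ = [
    "read_gravimetric_csv",
    "read_direct_csv",
    "series_from_frame",
    "grid_from_frame",
    "write_json_records",
]

GRAVIMETRIC_COLUMNS = [
    "solvent_id",
    "T_K",
    "m_drug_g",
    "m_solv1_g",
    "m_solv2_g",
    "M_drug",
    "M_solv1",
    "M_solv2",
]
DIRECT_COLUMNS = ["solvent_id", "T_K", "w2", "x_exp"]


def _check_columns(df: pd.DataFrame, required: list[str], optional: set[str] = frozenset()) -> None:
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise InvalidInputError(f"CSV is missing required columns: {missing}")


def read_gravimetric_csv(path) -> pd.DataFrame:
    """Read gravimetric measurements; returns a direct-schema frame with
    computed ``w2`` and ``x_exp`` columns."""
    df = pd.read_csv(path)
    _check_columns(df, GRAVIMETRIC_COLUMNS)
    w2, x = [], []
    for row in df.itertuples():
        rec = GravimetricRecord(
            mass_drug=row.m_drug_g,
            mass_solvent1=row.m_solv1_g,
            mass_solvent2=row.m_solv2_g,
            molar_mass_drug=row.M_drug,
            molar_mass_solvent1=row.M_solv1,
            molar_mass_solvent2=row.M_solv2,
            temperature=row.T_K,
        )
        x.append(mole_fraction_ternary(rec))
        w2.append(cosolvent_fraction(row.m_solv2_g, row.m_solv1_g))
    return pd.DataFrame(
        {"solvent_id": df["solvent_id"], "T_K": df["T_K"], "w2": w2, "x_exp": x}
    )


def read_direct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DIRECT_COLUMNS, optional={"w2"})
    if "w2" not in df.columns:
        df = df.assign(w2=0.0)
    df["w2"] = df["w2"].fillna(0.0)
    return df[DIRECT_COLUMNS]


def series_from_frame(df: pd.DataFrame, solvent_id: str) -> TemperatureSeries:
    """Extract one solvent's temperature series from a direct-schema frame."""
    sub = df[df["solvent_id"] == solvent_id].sort_values("T_K")
    if sub.empty:
        raise InvalidInputError(f"no rows for solvent {solvent_id!r}")
    return TemperatureSeries(
        solvent_id=solvent_id,
        temperatures=sub["T_K"].to_numpy(float),
        x=sub["x_exp"].to_numpy(float),
    )


def grid_from_frame(df: pd.DataFrame, solvent_id: str | None = None) -> MixtureGrid:
    """Extract a mixture grid (all rows, or one ``solvent_id``'s rows)."""
    sub = df if solvent_id is None else df[df["solvent_id"] == solvent_id]
    if sub.empty:
        raise InvalidInputError("no rows to build a mixture grid from")
    return MixtureGrid(
        w2=sub["w2"].to_numpy(float),
        temperatures=sub["T_K"].to_numpy(float),
        x=sub["x_exp"].to_numpy(float),
    )


def write_json_records(path, records, provenance: dict | None = None) -> None:
    """Write records as JSON with an optional provenance header block."""
    payload = {"provenance": provenance or {}, "records": records}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
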