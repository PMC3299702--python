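"""CSV schemas and validated reading/writing of survey tables.

Settlement CSV columns: station_id, distance_km, island_id, panel_id,
total_gastropods, n_confirmed. Plankton CSV columns: station_id, distance_km,
tow_id, speed_knots, duration_s, net_diameter_m, examined_fraction,
counted_larvae, n_assayed, n_confirmed. Validation errors name the offending
CSV row (1-based, counting the header as row 1).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import PLANKTON_COLUMNS, SETTLEMENT_COLUMNS

__all__ = ["read_survey_csv", "write_survey_csv", "SchemaError"]

_SCHEMAS = {"settlement": SETTLEMENT_COLUMNS, "plankton": PLANKTON_COLUMNS}

_COUNT_COLUMNS = {
    "settlement": ["total_gastropods", "n_confirmed"],
    "plankton": ["counted_larvae", "n_assayed", "n_confirmed"],
}


class SchemaError(ValueError):
    """A survey table violates its documented schema."""


def _row_err(df_index: int, msg: str) -> SchemaError:
    # +2: header line plus 1-based numbering
    return SchemaError(f"row {df_index + 2}: {msg}")


def validate_survey(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown survey kind {kind!r}")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing column(s): {', '.join(missing)}")
    df = df[_SCHEMAS[kind]].copy()
    for col in _COUNT_COLUMNS[kind]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            raise _row_err(int(df.index[bad][0]), f"{col} must be a nonnegative integer")
        df[col] = vals.astype("int64")
    neg_d = pd.to_numeric(df["distance_km"], errors="coerce") <= 0
    if neg_d.any():
        raise _row_err(int(df.index[neg_d][0]), "distance_km must be > 0")
    if kind == "settlement":
        bad = df["n_confirmed"] > df["total_gastropods"]
        if bad.any():
            raise _row_err(
                int(df.index[bad][0]), "n_confirmed exceeds total_gastropods"
            )
    else:
        bad = df["n_assayed"] > df["counted_larvae"]
        if bad.any():
            raise _row_err(int(df.index[bad][0]), "n_assayed exceeds counted_larvae")
        bad = df["n_confirmed"] > df["n_assayed"]
        if bad.any():
            raise _row_err(int(df.index[bad][0]), "n_confirmed exceeds n_assayed")
        nonneg = ["speed_knots", "duration_s", "net_diameter_m"]
        for col in nonneg:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0)
            if bad.any():
                raise _row_err(int(df.index[bad][0]), f"{col} must be >= 0")
        frac = pd.to_numeric(df["examined_fraction"], errors="coerce")
        bad = frac.isna() | (frac <= 0) | (frac > 1)
        if bad.any():
            raise _row_err(
                int(df.index[bad][0]), "examined_fraction must lie in (0, 1]"
            )
    return df


def read_survey_csv(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a settlement or plankton survey table."""
    df = pd.read_csv(path)
    return validate_survey(df, kind)


def write_survey_csv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Validate and write a survey table (lossless round trip)."""
    validate_survey(df, kind).to_csv(path, index=False)
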