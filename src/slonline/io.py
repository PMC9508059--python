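"""CSV dialect for trial and response tables.

One row per trial; UTF-8; header row; '.' decimal separator.  The trial
columns are fixed and ordered; response tables add ``rt_s`` and
``correct``, and preprocessed tables may add ``nvar`` and ``rt_valid``.
Reading validates the schema and reports the first offending row for
malformed numerics (e.g. a ',' decimal separator).
"""

from __future__ import annotations

import pandas as pd

from .designs import TRIAL_COLUMNS
from .errors import SchemaError

NUMERIC_COLUMNS = {
    "run": int,
    "trial": int,
    "repetition": int,
    "iti_ms": float,
    "rt_s": float,
    "nvar": float,
}
BOOL_COLUMNS = ("correct", "rt_valid")
OPTIONAL_COLUMNS = ("rt_s", "correct", "nvar", "rt_valid")


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial/response table; round-trips through :func:`read_trials`."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write table, missing columns {missing}")
    cols = TRIAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read a trial/response CSV with strict schema validation."""
    try:
        raw = pd.read_csv(
            path, dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (expected a header row)") from None
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = raw[col]
        if col in NUMERIC_COLUMNS:
            parsed = pd.to_numeric(vals, errors="coerce")
            bad = parsed.isna() & (vals.str.strip() != "")
            if bad.any():
                i = int(bad.idxmax())
                raise SchemaError(
                    f"{path}: column {col!r}, row {i + 2}: "
                    f"cannot parse {vals.iloc[i]!r} as a number "
                    "(decimal separator must be '.')"
                )
            if NUMERIC_COLUMNS[col] is int and not parsed.isna().any():
                parsed = parsed.astype(int)
            out[col] = parsed
        elif col in BOOL_COLUMNS:
            mapping = {"True": True, "False": False, "1": True, "0": False}
            unknown = ~vals.isin(mapping)
            if unknown.any():
                i = int(unknown.idxmax())
                raise SchemaError(
                    f"{path}: column {col!r}, row {i + 2}: "
                    f"cannot parse {vals.iloc[i]!r} as a boolean"
                )
            out[col] = vals.map(mapping).astype(bool)
        else:
            out[col] = vals
    ordered = TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]
    return out[ordered]
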