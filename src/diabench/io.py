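"""CSV round-tripping of patient records and YAML configuration loading.

The cohort CSV has one row per patient and the fixed header of
:data:`diabench.cohort.RECORD_COLUMNS`; missing cells are empty fields.
Booleans are written as ``True``/``False``; ``severe_hypo`` as ``1.0``/``0.0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .cohort import RECORD_COLUMNS
from .design import CATEGORY_LEVELS

__all__ = ["write_cohort", "load_records", "load_config_yaml", "ParseError"]


class ParseError(ValueError):
    """Malformed cohort CSV (unknown column or out-of-range value)."""


_BOOL_FIELDS = ("on_insulin", "fasting_at_lipids")
_NUMERIC_FIELDS = ("age", "duration", "hba1c", "ldl_ch", "sbp", "severe_hypo")


def write_cohort(records: pd.DataFrame, path) -> None:
    records.reindex(columns=RECORD_COLUMNS).to_csv(path, index=False)


def _parse_bool(series: pd.Series, name: str):
    mapping = {"True": True, "False": False, "true": True, "false": False,
               "1": True, "0": False, True: True, False: False}
    out = []
    for i, v in enumerate(series):
        if pd.isna(v) or v == "":
            out.append(np.nan)
        elif v in mapping:
            out.append(mapping[v])
        else:
            raise ParseError(f"row {i + 2}: bad boolean {v!r} in column {name}")
    return pd.Series(out, index=series.index, dtype=object)


def load_records(path) -> pd.DataFrame:
    """Read a cohort CSV back into the typed record frame.

    Validates the header and every categorical cell; errors carry the
    1-based file row number (header = row 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in RECORD_COLUMNS]
    if unknown:
        raise ParseError(f"unknown column(s): {unknown}")
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing column(s): {missing_cols}")
    df = df.replace("", np.nan)
    out = pd.DataFrame(index=df.index)
    out["centre_id"] = df["centre_id"]
    out["diabetes_type"] = df["diabetes_type"]
    for i, v in enumerate(df["diabetes_type"]):
        if pd.notna(v) and v not in ("t1dm", "t2dm"):
            raise ParseError(f"row {i + 2}: bad diabetes_type {v!r}")
    for fld, levels in CATEGORY_LEVELS.items():
        for i, v in enumerate(df[fld]):
            if pd.notna(v) and v not in levels:
                raise ParseError(f"row {i + 2}: bad {fld} {v!r}")
        out[fld] = df[fld]
    for fld in _NUMERIC_FIELDS:
        try:
            out[fld] = pd.to_numeric(df[fld])
        except (TypeError, ValueError) as exc:
            bad = df[fld][pd.to_numeric(df[fld], errors="coerce").isna() & df[fld].notna()]
            row = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"row {row}: non-numeric {fld}") from exc
    for fld in _BOOL_FIELDS:
        out[fld] = _parse_bool(df[fld], fld)
    out["age"] = out["age"].astype("Int64").astype(float)
    return out.reindex(columns=RECORD_COLUMNS)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError("config YAML must be a mapping")
    return data
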