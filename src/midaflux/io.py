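"""Validated tabular IO: schema-checked readers and deterministic writers."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "PEPTIDE_SCHEMA", "LIPID_SCHEMA",
           "BODY_WATER_SCHEMA", "STANDARDS_SCHEMA", "PATHWAY_MAP_SCHEMA"]


class SchemaError(ValueError):
    """A table failed validation (missing column, non-numeric value, ...)."""


# (required columns, numeric columns) per table kind
PEPTIDE_SCHEMA = (
    ("accession", "peptide", "animal", "M0", "M1", "M2", "M3"),
    ("M0", "M1", "M2", "M3"),
)
LIPID_SCHEMA = (
    ("animal", "fraction", "M0", "M1", "M2",
     "baseline_M0", "baseline_M1", "baseline_M2"),
    ("M0", "M1", "M2", "baseline_M0", "baseline_M1", "baseline_M2"),
)
BODY_WATER_SCHEMA = (("animal", "signal"), ("signal",))
STANDARDS_SCHEMA = (("enrichment", "signal"), ("enrichment", "signal"))
PATHWAY_MAP_SCHEMA = (("accession", "pathway_id", "pathway_name"), ())


def read_table(
    path: Path | str,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV/CSV table and validate its schema.

    The delimiter is sniffed (tab default); the header may be in any column
    order and unknown columns are preserved.  Missing mandatory columns and
    non-numeric values in numeric columns are rejected with the offending
    column/row named.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    if df.shape[1] == 1 and sep == "\t" and "," in df.columns[0]:
        df = pd.read_csv(path, sep=",", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = converted
    return df


def write_table(df: pd.DataFrame, path: Path | str, *, sort: bool = True) -> None:
    """Write a TSV deterministically: stable row order, 6-significant-digit floats."""
    path = Path(path)
    out = df.copy()
    if sort and len(out):
        keys = [c for c in out.columns
                if out[c].dtype == object or c in ("accession", "animal", "pathway_id")]
        if keys:
            out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
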