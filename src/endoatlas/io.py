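"""Reading and writing the package's tab-separated table dialects.

All tables are TSV with a header row, genes as rows in a ``gene`` column,
UTF-8, and ``NA`` as the missing-value sentinel. TSV rather than CSV so
that gene symbols containing commas can never corrupt a row.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import ALL_REGIONS, BRAIN_REGIONS, SUBFIELDS, SchemaError

NA = "NA"

#: Column schemas for the table kinds the pipeline exchanges.
SCHEMAS: dict[str, dict] = {
    "intensity": {"required": ["gene"], "numeric": list(ALL_REGIONS), "min": 0.0, "max": 255.0},
    "normalized": {"required": ["gene"], "numeric": list(ALL_REGIONS), "min": 0.0, "max": 100.0},
    "fpkm": {"required": ["gene"], "numeric": list(SUBFIELDS), "min": 0.0, "max": None},
    "groups": {"required": ["gene", "group"], "numeric": [], "min": None, "max": None},
    "effects": {"required": ["gene", "group", "ltp", "neurogenesis"],
                "numeric": ["ltp", "neurogenesis"], "min": -1.0, "max": 1.0},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against one of the named schemas.

    Raises :class:`SchemaError` naming the file, row and column for any
    violation (missing column, duplicate gene symbol, out-of-range value).
    """
    path = Path(path)
    spec = _schema(schema)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, na_values=[NA], keep_default_na=False)
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate gene symbol '{dup.iloc[0]}'")
    for col in spec["numeric"]:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{path}: row {row + 2}, column '{col}': non-numeric value {df[col].iloc[row]!r}")
        df[col] = vals
        for bound, op, word in ((spec["min"], np.less, "below"), (spec["max"], np.greater, "above")):
            if bound is None:
                continue
            out = vals.notna() & op(vals, bound)
            if out.any():
                row = int(np.flatnonzero(out.to_numpy())[0])
                raise SchemaError(
                    f"{path}: row {row + 2}, column '{col}': value {vals.iloc[row]} {word} bound {bound}"
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table in the TSV dialect (``NA`` for missing, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def require_columns(df: pd.DataFrame, cols: Sequence[str], what: str = "table") -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a reproducible per-stage random generator from one root seed.

    The stage name is folded in through CRC-32 so that every pipeline
    stage draws from its own substream regardless of execution order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def _schema(name: str) -> dict:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise SchemaError(f"unknown table schema '{name}'") from None


__all__ = ["read_table", "write_table", "require_columns", "stage_rng", "NA", "SCHEMAS"]
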