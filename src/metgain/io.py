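"""Reading and writing the long-format plot records and site metadata.

Both tables are plain CSV.  ``records.csv`` has the header
``genotype,site,year,rep,subblock,yield`` (yields in Mg ha^-1);
``sites.csv`` carries the site metadata used for megaenvironment
classification.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .simulate import META_COLUMNS, RECORD_COLUMNS

RECORDS_FILE = "records.csv"
META_FILE = "sites.csv"

_INT_COLS = ("year", "rep", "subblock")


def write_records(records: pd.DataFrame, meta: pd.DataFrame | None, path: str) -> None:
    """Write plot records (and optionally site metadata) under directory *path*."""
    os.makedirs(path, exist_ok=True)
    validate_records(records)
    records.to_csv(os.path.join(path, RECORDS_FILE), index=False)
    if meta is not None:
        meta.to_csv(os.path.join(path, META_FILE), index=False)


def _coerce(df: pd.DataFrame, col: str, kind: str, fname: str) -> pd.Series:
    try:
        return df[col].astype(int if kind == "int" else float)
    except (ValueError, TypeError):
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = conv.index[conv.isna() & df[col].notna()]
        # +2: 1-based line numbers plus the header line
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise ParseError(f"{fname}: line {line}: cannot parse {col!r} value "
                         f"{df[col].iloc[bad[0]]!r}") from None


def read_records(path: str, n_subblocks: int | None = None):
    """Read ``(records, meta)`` from directory *path*; meta may be None.

    Raises :class:`ParseError` for malformed rows and
    :class:`ValidationError` for structural violations (duplicate plots,
    out-of-range sub-block labels, non-positive yields).
    """
    rec_path = os.path.join(path, RECORDS_FILE)
    df = pd.read_csv(rec_path, dtype=str)
    missing_cols = set(RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{rec_path}: missing columns {sorted(missing_cols)}")
    out = pd.DataFrame({
        "genotype": df["genotype"].astype(str),
        "site": df["site"].astype(str),
    })
    for col in _INT_COLS:
        out[col] = _coerce(df, col, "int", rec_path)
    out["yield"] = _coerce(df, "yield", "float", rec_path)
    validate_records(out, n_subblocks=n_subblocks)
    meta = None
    meta_path = os.path.join(path, META_FILE)
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path)
        missing_cols = set(META_COLUMNS) - set(meta.columns)
        if missing_cols:
            raise ParseError(f"{meta_path}: missing columns {sorted(missing_cols)}")
        meta["irrigated"] = meta["irrigated"].astype(bool)
    return out, meta


def validate_records(records: pd.DataFrame, n_subblocks: int | None = None) -> None:
    """Structural checks on a plot-record table."""
    missing_cols = set(RECORD_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValidationError(f"records missing columns {sorted(missing_cols)}")
    if not np.all(records["yield"].to_numpy() > 0):
        bad = records.index[records["yield"] <= 0][0]
        raise ValidationError(f"non-positive yield at row {bad}")
    dup = records.duplicated(subset=["genotype", "site", "year", "rep"])
    if dup.any():
        row = records[dup].iloc[0]
        raise ValidationError(
            "duplicate plot for genotype "
            f"{row['genotype']!r} at site {row['site']!r} year {row['year']} "
            f"rep {row['rep']}"
        )
    if n_subblocks is not None:
        bad = records[(records["subblock"] < 1) | (records["subblock"] > n_subblocks)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"subblock {row['subblock']} outside 1..{n_subblocks} "
                f"(site {row['site']!r}, rep {row['rep']})"
            )
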