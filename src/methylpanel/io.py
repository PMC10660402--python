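"""Table readers and writers.

TSV is the canonical on-disk dialect (CSV selectable).  qPCR exports
write channels that never crossed threshold as the literal string
``Undetermined``; on read these (and ``NA``) become NaN, the in-memory
undetermined sentinel, and on write NaN CTs become ``Undetermined``
again, so a round trip preserves content.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("methylpanel")

UNDETERMINED_STRINGS = ("Undetermined", "NA", "")

WELL_COLUMNS = ["sample_id", "group", "well", "ct_msept9", "ct_malx4", "ct_msdc2", "ct_actb"]
CT_COLUMNS = ["ct_msept9", "ct_malx4", "ct_msdc2", "ct_actb"]

__all__ = [
    "read_well_table",
    "write_well_table",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_calls",
    "write_calls",
]


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_well_table(
    path: str | Path,
    dialect: str = "tsv",
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a long well table, mapping Undetermined CTs to NaN.

    ``column_map`` renames exported columns to the canonical schema
    (e.g. ``{"Sample Name": "sample_id"}``).  Raises on missing
    columns, non-numeric CT entries and duplicate (sample, well) rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty and not df.columns.tolist():
        logger.warning("empty well table at %s", path)
        return pd.DataFrame(columns=WELL_COLUMNS)
    missing = [c for c in WELL_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in CT_COLUMNS:
        raw = df[col].str.strip()
        blank = raw.isin(UNDETERMINED_STRINGS)
        numeric = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = (~blank) & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric CT {raw.iloc[row]!r} in column {col}, row {row}"
            )
        df[col] = numeric
    df["well"] = pd.to_numeric(df["well"]).astype(int)
    dup = df.duplicated(subset=["sample_id", "well"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (sample, well) row ({row['sample_id']}, {row['well']})"
        )
    logger.info("read %d well rows from %s", len(df), path)
    return df


def write_well_table(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write a well table, NaN CTs as the literal ``Undetermined``."""
    out = df.copy()
    for col in CT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "Undetermined" if pd.isna(v) else format(float(v), "g")
            )
    out.to_csv(path, sep=_sep(dialect), index=False)


def read_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a feature × sample matrix (first column is the feature id)."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    logger.info("read %d × %d matrix from %s", df.shape[0], df.shape[1], path)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    df.to_csv(path, sep=_sep(dialect))


def read_labels(path: str | Path, dialect: str = "tsv") -> pd.Series:
    """Read a two-column sample/label table into a Series."""
    df = pd.read_csv(path, sep=_sep(dialect))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label table needs two columns")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels(labels: pd.Series, path: str | Path, dialect: str = "tsv") -> None:
    labels.rename("group").rename_axis("sample_id").to_frame().reset_index().to_csv(
        path, sep=_sep(dialect), index=False
    )


def read_calls(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), keep_default_na=False)
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ValueError(f"{path}: call table needs sample_id and status columns")
    return df


def write_calls(calls: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    calls.to_csv(path, sep=_sep(dialect), index=False)
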