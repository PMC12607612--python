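"""CSV schemas and validated readers/writers for the pipeline's tables.

All interchange is plain UTF-8 CSV with a header row; every numeric column
name carries its unit.  Readers validate eagerly and report the offending
row index, so schema problems surface at the file boundary rather than deep
in a computation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .compounds import COMPOUNDS

logger = logging.getLogger("pahrisk")

SURVEY_COLUMNS = ["commodity", "sample_id", "compound", "concentration", "censored", "loq"]


class SchemaError(ValueError):
    """A CSV violates its documented schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format survey table.

    Columns: commodity, sample_id, compound, concentration (µg/kg),
    censored (bool), loq (µg/kg).  Unknown compound labels and negative
    concentrations are rejected with the first offending row index.
    """
    df = pd.read_csv(path)
    if df.empty and len(df.columns) > 0:
        logger.warning("%s: header-only survey file, no records", path)
        _require_columns(df, SURVEY_COLUMNS, path)
        return df
    _require_columns(df, SURVEY_COLUMNS, path)
    bad = ~df["compound"].isin(COMPOUNDS)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: row {row}: unknown compound {df.loc[row, 'compound']!r}; "
            f"valid labels are {', '.join(COMPOUNDS)}"
        )
    neg = df["concentration"] < 0
    if neg.any():
        row = int(df.index[neg][0])
        raise SchemaError(
            f"{path}: row {row}: negative concentration "
            f"{df.loc[row, 'concentration']}"
        )
    df["censored"] = df["censored"].astype(bool)
    inconsistent = df["censored"] & (df["concentration"] != 0)
    if inconsistent.any():
        row = int(df.index[inconsistent][0])
        raise SchemaError(f"{path}: row {row}: censored record with nonzero concentration")
    return df


def write_survey_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=SURVEY_COLUMNS)


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["level", "analyte_area", "is_area"], path)
    if (df["level"] <= 0).any():
        row = int(df.index[df["level"] <= 0][0])
        raise SchemaError(f"{path}: row {row}: non-positive calibration level")
    return df


def read_recovery_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["day", "level", "replicate", "measured"], path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table; floats at full precision for reproducibility."""
    df.to_csv(path, index=False)
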