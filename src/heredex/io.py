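"""Readers and writers for pair data and result tables.

All tabular I/O is CSV (UTF-8, comma-separated, mandatory header, '.'
decimal point) via pandas, or JSON mirroring the in-memory field names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import HeredexError, ShapeError, UsageError
from .expectation import ReTableRow
from .risk import RiskEstimate

__all__ = [
    "PAIR_COLUMNS",
    "ParseError",
    "PairData",
    "read_pairs",
    "write_pairs",
    "re_table_to_frame",
    "risk_table_to_frame",
    "write_table",
]

PAIR_COLUMNS = ("family_id", "relative_value", "proband_value")
MODES = ("continuous", "binary")


class ParseError(HeredexError):
    """A pairs file failed validation; the message names the line."""


@dataclass(frozen=True)
class PairData:
    """Validated relative/proband pair values loaded from (or bound for) a file."""

    mode: str
    family_id: np.ndarray
    relative: np.ndarray
    proband: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise UsageError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not (len(self.family_id) == len(self.relative) == len(self.proband)):
            raise ShapeError("pair data columns differ in length")

    @property
    def n_pairs(self) -> int:
        return len(self.relative)


def read_pairs(path, mode: str = "continuous") -> PairData:
    """Load a pairs CSV with columns family_id, relative_value, proband_value.

    Raises :class:`ParseError` naming the first offending line for missing
    columns, non-numeric cells, missing values, or (in binary mode) values
    outside {0, 1}.  Line numbers count the header as line 1.
    """
    if mode not in MODES:
        raise UsageError(f"unknown mode {mode!r}; expected one of {MODES}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"family_id": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    values = {}
    for col in ("relative_value", "proband_value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ParseError(f"{path}: non-numeric or missing {col} at line {line}")
        if mode == "binary":
            nonbinary = ~numeric.isin((0, 1))
            if nonbinary.any():
                line = int(nonbinary.idxmax()) + 2
                raise ParseError(
                    f"{path}: binary-mode {col} must be 0 or 1, offending line {line}"
                )
        values[col] = numeric.to_numpy()
    return PairData(
        mode=mode,
        family_id=df["family_id"].to_numpy(),
        relative=values["relative_value"],
        proband=values["proband_value"],
    )


def write_pairs(data: PairData, path) -> None:
    df = pd.DataFrame(
        {
            "family_id": data.family_id,
            "relative_value": data.relative,
            "proband_value": data.proband,
        }
    )
    df.to_csv(path, index=False)


def re_table_to_frame(rows: list[ReTableRow]) -> pd.DataFrame:
    """Long-format expected-correlation table.

    Two rows per incidence (group Onset / No-disease), with columns
    incidence, relationship, group, incidence_in_children, re, method, n,
    seed.
    """
    records = []
    for row in rows:
        for group, inc in (
            ("Onset", row.incidence_onset),
            ("No-disease", row.incidence_nodisease),
        ):
            records.append(
                {
                    "incidence": row.incidence,
                    "relationship": row.relationship,
                    "group": group,
                    "incidence_in_children": inc,
                    "re": row.re,
                    "method": row.method,
                    "n": row.n_families,
                    "seed": row.seed,
                }
            )
    return pd.DataFrame.from_records(records)


def risk_table_to_frame(estimates: list[RiskEstimate]) -> pd.DataFrame:
    return pd.DataFrame.from_records([e.to_dict() for e in estimates])


def write_table(df: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write a result table as CSV or JSON (records orientation)."""
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise UsageError(f"unknown output format {fmt!r}; expected 'csv' or 'json'")
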