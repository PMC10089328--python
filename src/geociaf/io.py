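"""Child-table schema, CSV readers and small writers.

The child table is one row per under-five child: a region id resolvable
against the region graph, child age in months (0-59), mother's age in years
(15-49), optionally the three anthropometric z-scores (or a precomputed
binary ``ciaf`` column), and the categorical covariates of the survey
codebook with declared level sets and reference levels.

Handling of incomplete rows is complete-case: rows missing any model
variable are dropped with a logged count, mirroring how analytic samples
are reduced from eligible samples in the source surveys.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ChildTableSchema", "DEFAULT_SCHEMA", "read_children_csv", "data_digest"]


@dataclass(frozen=True)
class ChildTableSchema:
    """Declared levels (reference first) for each categorical variable."""

    categorical: dict[str, list[str]] = field(default_factory=dict)
    region_column: str = "region"
    age_columns: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"child_age": (0, 59), "mother_age": (15, 49)}
    )
    zscore_columns: tuple[str, ...] = ("haz", "whz", "waz")
    outcome_column: str = "ciaf"

    def reference(self, var: str) -> str:
        return self.categorical[var][0]

    def levels(self, var: str) -> list[str]:
        return list(self.categorical[var])


#: Survey codebook: levels with the reference level first.
DEFAULT_SCHEMA = ChildTableSchema(
    categorical={
        "diarrhoea": ["no", "yes"],
        "cough": ["no", "yes"],
        "fever": ["no", "yes"],
        "vitamin_a": ["no", "yes"],
        "birth_order": ["1st", "2nd-3rd", "4th+"],
        "gender": ["female", "male"],
        "size_at_birth": ["very_small", "small", "average_or_larger"],
        "breastfeeding": ["no", "yes"],
        "education": ["none", "primary", "secondary+"],
        "bmi": ["normal", "thin", "obese"],
        "working": ["no", "yes"],
        "toilet": ["unimproved", "improved"],
        "water": ["unimproved", "improved"],
        "residence": ["rural", "urban"],
        "wealth": ["poorest", "poorer", "middle", "richer", "richest"],
        "media_exposure": ["no", "yes"],
    }
)


def read_children_csv(
    path: str | Path,
    schema: ChildTableSchema = DEFAULT_SCHEMA,
    required: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a child table.

    ``required`` names the model variables (defaults to every column present
    that the schema knows about, plus region and ages).  Rows with missing
    values in required columns are dropped with a logged count; unknown
    categorical levels and malformed numerics are hard errors naming the
    offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={schema.region_column: str})
    present_cat = [c for c in schema.categorical if c in df.columns]
    if required is None:
        required = (
            [schema.region_column]
            + [c for c in schema.age_columns if c in df.columns]
            + present_cat
        )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {missing_cols}")

    before = len(df)
    df = df.dropna(subset=[c for c in required])
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d incomplete rows (complete-case analysis)", dropped)

    for col in present_cat:
        allowed = set(schema.categorical[col])
        vals = df[col].astype(str)
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"unknown level {vals[bad].iloc[0]!r} in column {col!r} "
                f"(row {row}); allowed: {sorted(allowed)}"
            )
        df[col] = vals

    for col, (lo, hi) in schema.age_columns.items():
        if col not in df.columns:
            continue
        try:
            v = df[col].astype(float)
        except ValueError as exc:
            raise ValueError(f"malformed numeric value in column {col!r}") from exc
        out_of_range = (v < lo) | (v > hi)
        if out_of_range.any():
            row = int(df.index[out_of_range][0])
            raise ValueError(
                f"{col} value {v[out_of_range].iloc[0]} out of range "
                f"[{lo}, {hi}] (row {row})"
            )
        df[col] = v

    for col in schema.zscore_columns:
        if col in df.columns:
            df[col] = df[col].astype(float)
    if schema.outcome_column in df.columns:
        y = df[schema.outcome_column].astype(float)
        if not np.isin(y.dropna(), (0.0, 1.0)).all():
            raise ValueError(f"outcome column {schema.outcome_column!r} must be binary")
        df[schema.outcome_column] = y.astype("Int64")

    return df.reset_index(drop=True)


def data_digest(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame (for run manifests)."""
    h = hashlib.sha256()
    h.update(",".join(map(str, df.columns)).encode())
    h.update(pd.util.hash_pandas_object(df, index=False).values.tobytes())
    return h.hexdigest()[:16]
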