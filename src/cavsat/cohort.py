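"""Cohort table schema, validation and CSV round-trip.

A cohort is a plain :class:`pandas.DataFrame` with one row per admission.
The on-disk format is a strict UTF-8 CSV with a single header row and the
columns in :data:`COLUMNS`; unknown extra columns are preserved on read but
ignored by every analysis stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: The 17 baseline matching covariates: demographics, Wells score and the
#: 12 admission coagulation/haematology labs.
COVARIATES: tuple[str, ...] = (
    "age",
    "gender",
    "height_cm",
    "weight_kg",
    "wells",
    "wbc",
    "rbc",
    "hgb",
    "plt",
    "hct",
    "pt",
    "inr",
    "aptt",
    "tt",
    "fib",
    "ddimer",
    "fdp",
)

#: Covariates treated as binary (0/1) in balance metrics and models.
BINARY_COVARIATES: frozenset[str] = frozenset({"gender"})

#: Raw outcome fields carried by every record.
RAW_OUTCOMES: tuple[str, ...] = ("score_day1", "score_discharge", "los_days", "cost_cny")

#: Full CSV column order.
COLUMNS: tuple[str, ...] = ("id", "arm") + COVARIATES + RAW_OUTCOMES

ARMS = ("SAT", "CAV")
TREATED_ARM = "CAV"

_NUMERIC = tuple(c for c in COLUMNS if c not in ("id", "arm", "gender"))
_POSITIVE = (
    "height_cm", "weight_kg", "wbc", "rbc", "hgb", "plt", "hct",
    "pt", "inr", "aptt", "tt", "fib", "ddimer", "fdp", "los_days",
)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema; collects all problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n" + "\n".join(self.problems))


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema, listing every violation.

    Returns the frame with numeric columns coerced to float.  Raises
    :class:`CohortValidationError` naming each offending row and column.
    """
    problems: list[str] = []
    for col in COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column: {col}")
    if problems:
        raise CohortValidationError(problems)

    df = df.copy()
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        problems.append(f"duplicate id(s): {dupes}")
    bad_arm = ~df["arm"].isin(ARMS)
    for idx in df.index[bad_arm]:
        problems.append(f"row {idx}: arm must be one of {ARMS}, got {df.at[idx, 'arm']!r}")
    bad_gender = ~df["gender"].isin(("F", "M"))
    for idx in df.index[bad_gender]:
        problems.append(f"row {idx}: gender must be 'F' or 'M', got {df.at[idx, 'gender']!r}")

    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        for idx in df.index[bad]:
            problems.append(f"row {idx}: column {col} is not numeric ({df.at[idx, col]!r})")
        df[col] = coerced

    if not problems:
        for col in _POSITIVE:
            neg = df[col] <= 0
            for idx in df.index[neg]:
                problems.append(f"row {idx}: column {col} must be > 0, got {df.at[idx, col]}")
        neg_scores = (df["score_day1"] < 0) | (df["score_discharge"] < 0) | (df["cost_cny"] < 0)
        for idx in df.index[neg_scores]:
            problems.append(f"row {idx}: scores and cost must be >= 0")
    if problems:
        raise CohortValidationError(problems)
    return df


def covariate_matrix(df: pd.DataFrame, covariates: tuple[str, ...] | list[str] = COVARIATES) -> pd.DataFrame:
    """Numeric covariate design matrix: gender coded 0/1 (M=1), labs as-is."""
    out = {}
    for c in covariates:
        if c == "gender":
            out[c] = (df["gender"] == "M").astype(float) if df["gender"].dtype == object else df["gender"].astype(float)
        else:
            out[c] = df[c].astype(float)
    return pd.DataFrame(out, index=df.index)


def treatment_indicator(df: pd.DataFrame) -> np.ndarray:
    """0/1 array; 1 marks the CAV (treated) arm."""
    return (df["arm"] == TREATED_ARM).to_numpy(dtype=int)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path, dtype={"id": str, "arm": str, "gender": str})
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV in canonical column order (deterministic bytes)."""
    extra = [c for c in df.columns if c not in COLUMNS]
    df.loc[:, list(COLUMNS) + extra].to_csv(path, index=False, float_format="%.10g")
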