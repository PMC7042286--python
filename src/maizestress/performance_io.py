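"""Reading, validation and preprocessing of hybrid performance tables.

A performance table has one row per (hybrid, environment) trial with yield
in quintals/ha, the season dates, the irrigation category and eight soil
descriptors.  Preprocessing mirrors the cleaning applied to multi-location
trial data before environment-level modelling: rows with unknown irrigation
are dropped, rows whose harvest date does not follow planting are dropped,
and replicate (hybrid, environment) rows are collapsed to their mean yield.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import pandas as pd

from .stress_features import SOIL_FEATURES

logger = logging.getLogger(__name__)

IRRIGATION_LEVELS = ("none", "very_light", "light", "normal", "unknown")
PERCENT_SOIL = ("sand", "clay", "silt")

REQUIRED_COLUMNS = [
    "hybrid_id",
    "env_id",
    "yield",
    "planting_date",
    "harvest_date",
    "irrigation",
    *SOIL_FEATURES,
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EmptyDataError(ValueError):
    """No rows survive preprocessing."""


@dataclass
class PreprocessReport:
    """Row accounting for one preprocessing pass."""

    n_input: int = 0
    n_unknown_irrigation: int = 0
    n_invalid_dates: int = 0
    n_duplicates_collapsed: int = 0
    n_soil_values_imputed: int = 0
    n_output: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def load_performance(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and type a performance CSV.

    Returns ``(records, rejected)``: typed rows, and a per-row report of
    rows whose mandatory fields could not be parsed or violate basic
    invariants (negative yield, soil percentages outside [0, 100], unknown
    category spelling).  Missing columns raise :class:`SchemaError` naming
    the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"performance table missing column(s): {missing}")

    df = df.copy()
    df["yield"] = pd.to_numeric(df["yield"], errors="coerce")
    for col in ("planting_date", "harvest_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    df["irrigation"] = df["irrigation"].astype(str).str.strip().str.lower()
    for col in SOIL_FEATURES:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = pd.Series("", index=df.index)

    def flag(mask, reason):
        nonlocal reasons
        reasons[mask & (reasons == "")] = reason

    flag(df["yield"].isna(), "unparseable yield")
    flag(df["yield"] < 0, "negative yield")
    flag(df["planting_date"].isna(), "unparseable planting_date")
    flag(df["harvest_date"].isna(), "unparseable harvest_date")
    flag(~df["irrigation"].isin(IRRIGATION_LEVELS), "unrecognised irrigation")
    for col in PERCENT_SOIL:
        flag((df[col] < 0) | (df[col] > 100), f"{col} outside [0, 100]")

    bad = reasons != ""
    rejected = df[bad].assign(reason=reasons[bad])
    if bad.any():
        logger.warning("rejected %d malformed rows", int(bad.sum()))
    return df[~bad].reset_index(drop=True), rejected


def preprocess(records: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the standard cleaning rules to loaded performance records.

    1. drop rows with unknown irrigation;
    2. drop rows with harvest_date <= planting_date (a season of zero or
       negative length cannot be stage-split);
    3. median-impute missing soil values;
    4. collapse duplicate (hybrid, env) rows to one with mean yield.

    Idempotent; raises :class:`EmptyDataError` when nothing survives.
    """
    report = PreprocessReport(n_input=len(records))
    df = records.copy()

    unknown = df["irrigation"] == "unknown"
    report.n_unknown_irrigation = int(unknown.sum())
    df = df[~unknown]

    bad_dates = df["harvest_date"] <= df["planting_date"]
    report.n_invalid_dates = int(bad_dates.sum())
    df = df[~bad_dates]

    for col in SOIL_FEATURES:
        n_nan = int(df[col].isna().sum())
        if n_nan:
            df[col] = df[col].fillna(df[col].median())
            report.n_soil_values_imputed += n_nan

    n_before = len(df)
    agg = {c: "first" for c in df.columns if c not in ("hybrid_id", "env_id")}
    agg["yield"] = "mean"
    df = df.groupby(["hybrid_id", "env_id"], as_index=False, sort=False).agg(agg)
    df = df[records.columns]
    report.n_duplicates_collapsed = n_before - len(df)

    report.n_output = len(df)
    if report.n_output == 0:
        raise EmptyDataError("no data after preprocessing")
    logger.info(
        "preprocess: %d -> %d rows (%d unknown irrigation, %d invalid dates, "
        "%d duplicates collapsed)",
        report.n_input,
        report.n_output,
        report.n_unknown_irrigation,
        report.n_invalid_dates,
        report.n_duplicates_collapsed,
    )
    return df.reset_index(drop=True), report


def _modal(series: pd.Series):
    modes = series.mode()
    return modes.iloc[0] if len(modes) else series.iloc[0]


def environment_table(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Aggregate cleaned records to one row per environment.

    mean_yield is the arithmetic mean over the environment's hybrid yields.
    Dates, irrigation and soil are expected to be constant within an
    environment; conflicts resolve to the modal value with a warning.
    """
    env_cols = ["planting_date", "harvest_date", "irrigation", *SOIL_FEATURES]
    rows = []
    for env_id, grp in cleaned.groupby("env_id", sort=True):
        row = {"env_id": env_id}
        for col in env_cols:
            uniq = grp[col].dropna().unique()
            if len(uniq) > 1:
                warnings.warn(
                    f"environment {env_id}: conflicting values for {col}; "
                    "using the modal value",
                    stacklevel=2,
                )
            row[col] = _modal(grp[col])
        row["mean_yield"] = float(grp["yield"].mean())
        row["n_records"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
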