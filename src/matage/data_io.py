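"""Reading, validating and writing individual life-history tables.

The canonical on-disk format is a long-format CSV with one row per
individual per day of observation:

    individual_id, treatment, maternal_age, age_day, status, offspring

``treatment`` is ``AL`` (ad libitum) or ``LF`` (low food, chronic caloric
restriction); ``maternal_age`` is the age of the individual's mother at the
individual's birth, in days (a fixed attribute carried for life);
``age_day`` counts census days from 1, where day ``j`` covers the interval
``(j-1, j]`` since birth; ``status`` is ``alive``, ``dead`` or ``censored``;
``offspring`` is the number of live daughters counted at that census.

Records are ragged: an individual's rows run from ``age_day = 1`` up to the
day of its death or censoring (or its last observation, if the experiment
ended first).  At most one terminal ``dead``/``censored`` row is allowed and
offspring counts on that row must be zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

TREATMENTS = ("AL", "LF")
STATUSES = ("alive", "dead", "censored")

#: Canonical column names of a life-history table.
COLUMNS = [
    "individual_id",
    "treatment",
    "maternal_age",
    "age_day",
    "status",
    "offspring",
]


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """The table violates a life-history invariant.

    Attributes
    ----------
    individuals : list
        Identifiers of the offending individuals.
    """

    def __init__(self, message: str, individuals=()):
        super().__init__(message)
        self.individuals = list(individuals)


def validate_life_histories(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a life-history table and return it sorted canonically.

    Checks, per individual: consecutive ``age_day`` starting at 1; at most
    one terminal non-alive record, with every earlier record ``alive``;
    zero offspring on non-alive records; a single treatment and a single
    maternal age.  Raises :class:`ValidationError` naming the offending
    individuals, or :class:`SchemaError` if columns are missing.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    df = table.loc[:, COLUMNS].copy()
    if df["treatment"].isna().any() or ~df["treatment"].isin(TREATMENTS).all():
        bad = df.loc[~df["treatment"].isin(TREATMENTS), "treatment"].unique()
        raise ValidationError(f"unknown treatment labels: {list(bad)}")
    if ~df["status"].isin(STATUSES).all():
        bad = df.loc[~df["status"].isin(STATUSES), "status"].unique()
        raise ValidationError(f"unknown status labels: {list(bad)}")
    for col in ("maternal_age", "age_day", "offspring"):
        values = df[col]
        if values.isna().any():
            who = df.loc[values.isna(), "individual_id"].unique()
            raise ValidationError(f"missing {col} values", who)
        if not (values == values.astype(int)).all():
            raise ValidationError(f"non-integer {col} values")
        df[col] = values.astype(int)
    if (df["age_day"] < 1).any() or (df["maternal_age"] < 1).any():
        raise ValidationError("age_day and maternal_age must be >= 1")
    if (df["offspring"] < 0).any():
        who = df.loc[df["offspring"] < 0, "individual_id"].unique()
        raise ValidationError("negative offspring counts", who)

    df = df.sort_values(["individual_id", "age_day"], kind="stable")
    df = df.reset_index(drop=True)

    bad_ages, bad_terminal, bad_offspring, bad_attrs = [], [], [], []
    for ind, g in df.groupby("individual_id", sort=False):
        ages = g["age_day"].to_numpy()
        if ages[0] != 1 or not np.array_equal(ages, np.arange(1, len(ages) + 1)):
            bad_ages.append(ind)
        status = g["status"].to_numpy()
        if (status[:-1] != "alive").any():
            bad_terminal.append(ind)
        if (g.loc[g["status"] != "alive", "offspring"] != 0).any():
            bad_offspring.append(ind)
        if g["treatment"].nunique() > 1 or g["maternal_age"].nunique() > 1:
            bad_attrs.append(ind)
    if bad_ages:
        raise ValidationError(
            "age_day not consecutive from 1 for individuals: " f"{bad_ages}",
            bad_ages,
        )
    if bad_terminal:
        raise ValidationError(
            "records after a dead/censored record for individuals: "
            f"{bad_terminal}",
            bad_terminal,
        )
    if bad_offspring:
        raise ValidationError(
            "nonzero offspring on a non-alive record for individuals: "
            f"{bad_offspring}",
            bad_offspring,
        )
    if bad_attrs:
        raise ValidationError(
            "multiple treatments or maternal ages for individuals: "
            f"{bad_attrs}",
            bad_attrs,
        )
    return df


def read_life_histories(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a life-history CSV and validate it.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    schema
        Optional mapping from the file's column names to the canonical
        names in :data:`COLUMNS`, for data laid out with other headers.

    Returns
    -------
    pandas.DataFrame
        Validated table sorted by ``(individual_id, age_day)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    if schema:
        df = df.rename(columns=dict(schema))
    return validate_life_histories(df)


def write_life_histories(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated life-history table as canonical CSV."""
    table = validate_life_histories(table)
    table.to_csv(path, index=False, encoding="utf-8")


def cohort_census(table: pd.DataFrame) -> pd.DataFrame:
    """Count individuals per (treatment, maternal_age) cell.

    Returns one row per cell with columns ``treatment``, ``maternal_age``
    and ``n``; the counts sum to the total number of individuals.
    """
    counts = (
        table.groupby(["treatment", "maternal_age"], sort=True)["individual_id"]
        .nunique()
        .rename("n")
        .reset_index()
    )
    return counts
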