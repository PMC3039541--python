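"""Cohort records and reference-survey category tables.

The unit of analysis is one participant: entry age and calendar year, elapsed
follow-up in years, a death indicator, a sampling weight correcting design
oversampling, a stratum matching the population life table, and baseline
categorical covariates.  The canonical in-memory container is a pandas
DataFrame with the columns below; :class:`CohortRecord` offers a record-level
view for small data and doctests.

Attained age during follow-up interval ``i`` is ``entry_age + i`` and the
attained calendar year is ``entry_year + i`` — annual intervals aligned to
the baseline survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "entry_age", "entry_year", "follow_up", "event", "weight", "stratum")


class CohortValidationError(ValueError):
    """Raised when cohort records violate their invariants."""


@dataclass
class CohortRecord:
    """One participant's follow-up summary plus baseline covariates."""

    id: str
    entry_age: int
    entry_year: int
    follow_up: float
    event: int
    weight: float = 1.0
    stratum: str = "all"
    covariates: dict[str, str] = field(default_factory=dict)


def validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants, raising :class:`CohortValidationError` with row numbers."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing cohort column(s): {missing}")
    if len(df) == 0:
        logger.warning("cohort file contains a header but no records")
        return df
    checks = [
        (df["follow_up"] < 0, "negative follow_up"),
        (~df["event"].isin([0, 1]), "event not in {0, 1}"),
        (df["weight"] <= 0, "weight <= 0"),
        (~np.isfinite(df["follow_up"]), "non-finite follow_up"),
    ]
    for bad, what in checks:
        if bad.any():
            i = bad.idxmax()
            raise CohortValidationError(f"{what} at row {i} (id={df.loc[i, 'id']!r})")
    return df


def cohort_frame(records) -> pd.DataFrame:
    """Coerce a DataFrame or an iterable of :class:`CohortRecord` to a validated frame."""
    if isinstance(records, pd.DataFrame):
        return validate_cohort_frame(records.reset_index(drop=True))
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in REQUIRED_COLUMNS}
        row.update(r.covariates)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return validate_cohort_frame(pd.DataFrame(rows))


def covariate_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in REQUIRED_COLUMNS]


def records_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    covs = covariate_columns(df)
    return [
        CohortRecord(
            id=str(row["id"]),
            entry_age=int(row["entry_age"]),
            entry_year=int(row["entry_year"]),
            follow_up=float(row["follow_up"]),
            event=int(row["event"]),
            weight=float(row["weight"]),
            stratum=str(row["stratum"]),
            covariates={c: row[c] for c in covs},
        )
        for _, row in df.iterrows()
    ]


def read_cohort(path, as_records: bool = False):
    """Read and validate a cohort CSV.

    Required columns ``id,entry_age,entry_year,follow_up,event,weight,stratum``;
    any remaining column is treated as a categorical covariate.  Returns a
    DataFrame by default, or ``list[CohortRecord]`` with ``as_records=True``.
    """
    df = validate_cohort_frame(pd.read_csv(path))
    return records_from_frame(df) if as_records else df


def write_cohort(records, path) -> None:
    cohort_frame(records).to_csv(path, index=False)


def censor_at(records, horizon: float):
    """Administratively censor follow-up at ``horizon`` years.

    Records with ``follow_up > horizon`` are truncated to the horizon with
    the event flag cleared; all others are returned unchanged.  Accepts and
    returns either container type.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if isinstance(records, pd.DataFrame):
        out = records.copy()
        over = out["follow_up"] > horizon
        out.loc[over, "follow_up"] = horizon
        out.loc[over, "event"] = 0
        return out
    out = []
    for r in records:
        if r.follow_up > horizon:
            r = CohortRecord(
                id=r.id, entry_age=r.entry_age, entry_year=r.entry_year,
                follow_up=horizon, event=0, weight=r.weight,
                stratum=r.stratum, covariates=dict(r.covariates),
            )
        out.append(r)
    return out


@dataclass
class CategoryTable:
    """Cohort-vs-reference counts for one categorical characteristic."""

    covariate: str
    categories: tuple[str, ...]
    cohort_counts: np.ndarray
    reference_counts: np.ndarray

    def __post_init__(self) -> None:
        self.cohort_counts = np.asarray(self.cohort_counts, dtype=float)
        self.reference_counts = np.asarray(self.reference_counts, dtype=float)
        k = len(self.categories)
        if self.cohort_counts.shape != (k,) or self.reference_counts.shape != (k,):
            raise ValueError(f"{self.covariate}: counts must match the {k} categories")
        if np.any(self.cohort_counts < 0) or np.any(self.reference_counts < 0):
            raise ValueError(f"{self.covariate}: counts must be non-negative")
        if self.cohort_counts.sum() <= 0 or self.reference_counts.sum() <= 0:
            raise ValueError(f"{self.covariate}: each side needs a positive total")


def read_category_tables(path) -> list[CategoryTable]:
    """Read ``covariate,category,cohort_count,reference_count`` CSV, one table per covariate."""
    df = pd.read_csv(path)
    need = {"covariate", "category", "cohort_count", "reference_count"}
    if not need.issubset(df.columns):
        raise ValueError(f"category table needs columns {sorted(need)}")
    return [
        CategoryTable(
            covariate=str(cov),
            categories=tuple(grp["category"].astype(str)),
            cohort_counts=grp["cohort_count"].to_numpy(),
            reference_counts=grp["reference_count"].to_numpy(),
        )
        for cov, grp in df.groupby("covariate", sort=False)
    ]
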