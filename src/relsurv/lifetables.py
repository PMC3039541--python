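"""Population life tables: annual death probabilities by stratum, calendar year and age.

National statistical offices publish complete life tables as annual death
probabilities ``q(x)`` — the probability that a person alive at exact age
``x`` dies before age ``x+1`` — stratified by sex, region and calendar
year.  This module loads such tables, validates them, and serves the two
derived quantities the rest of the pipeline needs:

* the annual *expected survival* ``p* = 1 - q``, used to accumulate
  expected survival curves for a cohort, and
* the *expected hazard* ``mu* = -ln(1 - q)``, the piecewise-constant
  force of mortality consistent with ``q``, used as the known baseline in
  relative-mortality regression.

The stored quantity is always ``q``; hazards are derived on demand.
Lookups clamp ages above the table's maximum to the terminal age (open-ended
terminal age groups are standard in published tables) and resolve calendar
years outside the table — or missing from a sparse table — to the nearest
available year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default CSV column names for :func:`read_lifetable`
DEFAULT_SCHEMA = {"stratum": "stratum", "year": "year", "age": "age", "q": "qx"}


class LifeTableError(ValueError):
    """Raised when a life table fails structural validation."""


@dataclass
class PopulationLifeTable:
    """Dense grid of annual death probabilities ``q[stratum, year, age]``.

    Parameters
    ----------
    strata
        Ordered stratum labels (e.g. State/Territory codes).
    years
        Sorted array of the calendar years present (need not be contiguous).
    ages
        Contiguous array of integer ages covered by every stratum-year.
    q
        Array of shape ``(len(strata), len(years), len(ages))`` with every
        value in ``[0, 1)``.
    """

    strata: tuple[str, ...]
    years: np.ndarray
    ages: np.ndarray
    q: np.ndarray
    _stratum_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.strata), len(self.years), len(self.ages)):
            raise LifeTableError(
                f"q has shape {self.q.shape}, expected "
                f"({len(self.strata)}, {len(self.years)}, {len(self.ages)})"
            )
        if np.any(np.diff(self.ages) != 1):
            raise LifeTableError("ages must form a contiguous integer range")
        if np.any(np.diff(self.years) <= 0):
            raise LifeTableError("years must be strictly increasing")
        bad = (self.q < 0) | (self.q >= 1) | ~np.isfinite(self.q)
        if np.any(bad):
            s, y, a = (idx[0] for idx in np.nonzero(bad))
            raise LifeTableError(
                f"q={self.q[s, y, a]!r} outside [0, 1) at "
                f"(stratum={self.strata[s]!r}, year={self.years[y]}, age={self.ages[a]})"
            )
        self._stratum_index = {s: i for i, s in enumerate(self.strata)}

    # -- ranges ---------------------------------------------------------

    @property
    def age_range(self) -> tuple[int, int]:
        return int(self.ages[0]), int(self.ages[-1])

    @property
    def year_range(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    # -- lookup ---------------------------------------------------------

    def stratum_id(self, stratum: str) -> int:
        try:
            return self._stratum_index[stratum]
        except KeyError:
            raise KeyError(
                f"unknown stratum {stratum!r}; table has {sorted(self.strata)}"
            ) from None

    def _resolve_years(self, years: np.ndarray) -> np.ndarray:
        """Index of the nearest available calendar year (ties go downward)."""
        pos = np.searchsorted(self.years, years)
        pos = np.clip(pos, 0, len(self.years) - 1)
        lo = np.clip(pos - 1, 0, len(self.years) - 1)
        use_lo = np.abs(self.years[lo] - years) <= np.abs(self.years[pos] - years)
        return np.where(use_lo, lo, pos)

    def q_values(
        self,
        stratum_ids: np.ndarray | int,
        years: np.ndarray | int,
        ages: np.ndarray | int,
    ) -> np.ndarray:
        """Vectorised ``q`` lookup with age clamping and nearest-year fallback."""
        sid = np.asarray(stratum_ids, dtype=int)
        years = np.asarray(years, dtype=int)
        ages = np.asarray(ages, dtype=int)
        yidx = self._resolve_years(years)
        aidx = np.clip(ages, self.ages[0], self.ages[-1]) - self.ages[0]
        return self.q[sid, yidx, aidx]

    def annual_q(self, stratum: str, year: int, age: int) -> float:
        """Annual death probability for one (stratum, year, age) cell."""
        return float(self.q_values(self.stratum_id(stratum), year, age))

    def annual_expected_survival(self, stratum: str, year: int, age: int) -> float:
        """Expected one-year survival ``p* = 1 - q``."""
        return 1.0 - self.annual_q(stratum, year, age)

    def expected_hazard(self, stratum: str, year: int, age: int) -> float:
        """Expected annual hazard ``mu* = -ln(1 - q)``, per year."""
        return float(-np.log1p(-self.annual_q(stratum, year, age)))

    def hazard_values(self, stratum_ids, years, ages) -> np.ndarray:
        """Vectorised expected hazards (see :meth:`q_values`)."""
        return -np.log1p(-self.q_values(stratum_ids, years, ages))

    # -- I/O ------------------------------------------------------------

    def to_frame(self, schema: dict[str, str] | None = None) -> pd.DataFrame:
        schema = {**DEFAULT_SCHEMA, **(schema or {})}
        s, y, a = np.meshgrid(
            np.arange(len(self.strata)), self.years, self.ages, indexing="ij"
        )
        return pd.DataFrame(
            {
                schema["stratum"]: np.asarray(self.strata)[s.ravel()],
                schema["year"]: y.ravel(),
                schema["age"]: a.ravel(),
                schema["q"]: self.q.ravel(),
            }
        )


def lifetable_from_frame(
    df: pd.DataFrame, schema: dict[str, str] | None = None
) -> PopulationLifeTable:
    """Build a validated :class:`PopulationLifeTable` from a long-format frame."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise LifeTableError(f"missing life-table column(s): {missing}")
    df = df.rename(columns={v: k for k, v in schema.items()})

    dup = df.duplicated(subset=["stratum", "year", "age"])
    if dup.any():
        row = df[dup].iloc[0]
        raise LifeTableError(
            f"duplicate (stratum, year, age) key at row {dup.idxmax()}: "
            f"({row['stratum']!r}, {row['year']}, {row['age']})"
        )
    bad = (df["q"] < 0) | (df["q"] >= 1) | ~np.isfinite(df["q"])
    if bad.any():
        i = bad.idxmax()
        raise LifeTableError(f"q={df.loc[i, 'q']!r} outside [0, 1) at row {i}")

    strata = tuple(pd.unique(df["stratum"]))
    years = np.sort(df["year"].unique())
    ages = np.sort(df["age"].unique())
    if np.any(np.diff(ages) != 1):
        gap = ages[np.nonzero(np.diff(ages) != 1)[0][0]]
        raise LifeTableError(f"ages are not contiguous: gap after age {gap}")

    for (s, y), grp in df.groupby(["stratum", "year"], sort=False):
        got = np.sort(grp["age"].to_numpy())
        if len(got) != len(ages) or np.any(got != ages):
            raise LifeTableError(
                f"stratum {s!r}, year {y}: ages {got.tolist()} do not cover "
                f"the common contiguous range {ages[0]}..{ages[-1]}"
            )

    grid = (
        df.set_index(["stratum", "year", "age"])["q"]
        .unstack(["year", "age"])
        .loc[list(strata)]
        .to_numpy()
        .reshape(len(strata), len(years), len(ages))
    )
    return PopulationLifeTable(strata=strata, years=years, ages=ages, q=grid)


def read_lifetable(
    path, schema: dict[str, str] | None = None
) -> PopulationLifeTable:
    """Read a life-table CSV (columns ``stratum,year,age,qx`` by default)."""
    return lifetable_from_frame(pd.read_csv(path), schema=schema)


def write_lifetable(table: PopulationLifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
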