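"""Weighted cohort life tables and Ederer II relative survival.

Relative survival compares a cohort's observed survival with the survival it
would have experienced under the mortality of a matched general population.
For annual intervals ``[i, i+1)`` since entry the actuarial estimator is

* at risk at interval start ``L``, deaths ``D``, withdrawals ``W``;
* effective at-risk ``L' = L - W/2`` (withdrawals assumed uniform over the
  interval) and interval observed survival ``P = 1 - D/L'``;
* cumulative observed survival by the product recursion
  ``CP(i+1) = CP(i) * P(i)``, ``CP(0) = 1``;
* expected deaths ``D*`` by the Ederer II convention — summed over the
  individuals actually at risk at the interval start, each contributing its
  own population death probability ``q*`` at its attained age, attained
  calendar year and stratum (half a contribution if withdrawn within the
  interval, mirroring ``L'``) — giving ``P* = 1 - D*/L'`` and ``CP*`` by the
  same recursion;
* interval and cumulative relative survival ``R = P/P*``, ``CR = CP/CP*``.

With sampling weights every count is a weighted sum and the formulas apply
unchanged; ratios are invariant to rescaling all weights.

Confidence intervals for ``CR`` use the Greenwood variance of ``log CP``,
``var = sum_k D_k / (L'_k (L'_k - D_k))``, treating the expected curve as
fixed — the standard large-cohort approximation in relative-survival work.

Interval membership is half-open: a death at exactly ``t = k*width`` counts
in interval ``k``.  A *censoring* at exactly ``t = k*width`` (``t > 0``) is
assigned to interval ``k - 1``: such a record was fully exposed through the
preceding interval and never entered the next, which is how administrative
end-of-study censoring appears in published cohort life tables.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import cohort_frame
from .lifetables import PopulationLifeTable

logger = logging.getLogger(__name__)

#: columns of a full life-table result, in output order
TABLE_COLUMNS = [
    "interval", "start", "end", "L", "D", "W", "L_eff",
    "P", "CP", "D_star", "P_star", "CP_star", "R", "CR", "ci_low", "ci_high",
]


def _exit_intervals(t: np.ndarray, event: np.ndarray, width: float) -> np.ndarray:
    """Interval index in which each record exits follow-up."""
    idx = np.floor(t / width).astype(int)
    on_boundary = (t > 0) & (np.abs(t - idx * width) <= 1e-9)
    idx = np.where(on_boundary & (event == 0), idx - 1, idx)
    return idx


def tabulate_intervals(
    records, width: float = 1.0, weighted: bool = True
) -> pd.DataFrame:
    """Tabulate (L, D, W) per follow-up interval of the given width.

    Deaths and censorings contribute the record's sampling weight when
    ``weighted`` (else 1); ``L`` follows the recursion
    ``L(i+1) = L(i) - D(i) - W(i)`` from the (weighted) cohort size.
    """
    if width <= 0:
        raise ValueError("interval width must be positive")
    df = cohort_frame(records)
    if len(df) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    t = df["follow_up"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    w = df["weight"].to_numpy(dtype=float) if weighted else np.ones(len(df))

    idx = _exit_intervals(t, event, width)
    n_int = int(idx.max()) + 1
    D = np.bincount(idx[event == 1], weights=w[event == 1], minlength=n_int)
    W = np.bincount(idx[event == 0], weights=w[event == 0], minlength=n_int)
    L = np.empty(n_int)
    L[0] = w.sum()
    if n_int > 1:
        L[1:] = L[0] - np.cumsum(D + W)[:-1]
    return pd.DataFrame(
        {
            "interval": np.arange(n_int),
            "start": np.arange(n_int) * width,
            "end": (np.arange(n_int) + 1) * width,
            "L": L,
            "D": D,
            "W": W,
        }
    )


def observed_survival(counts: pd.DataFrame) -> pd.DataFrame:
    """Add effective at-risk ``L' = L - W/2``, interval ``P`` and cumulative ``CP``.

    Intervals whose effective at-risk is non-positive are dropped with a
    warning; ``D > L'`` is an error (more deaths than exposure).
    """
    out = counts.copy()
    out["L_eff"] = out["L"] - out["W"] / 2.0
    drop = out["L_eff"] <= 0
    if drop.any():
        logger.warning(
            "dropping %d interval(s) with non-positive effective at-risk", drop.sum()
        )
        out = out[~drop].copy()
    if (out["D"] > out["L_eff"]).any():
        i = int(out.loc[out["D"] > out["L_eff"], "interval"].iloc[0])
        raise ValueError(f"interval {i}: deaths exceed effective at-risk")
    out["P"] = 1.0 - out["D"] / out["L_eff"]
    out["CP"] = out["P"].cumprod()
    return out


def ederer2_expected(
    records,
    table: PopulationLifeTable,
    counts: pd.DataFrame,
    width: float = 1.0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Ederer II expected deaths and expected survival per interval.

    For interval ``i``, ``D*_i`` sums ``w_j * q*_ij`` over the records at
    risk at the interval start, where ``q*_ij`` is the life-table death
    probability at the record's attained age ``entry_age + i`` and attained
    year ``entry_year + i`` in its stratum; records withdrawn within the
    interval contribute half.  ``P* = 1 - D*/L'``; ``CP*`` by the product
    recursion.
    """
    df = cohort_frame(records)
    sid = np.array([table.stratum_id(s) for s in df["stratum"]])
    t = df["follow_up"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    w = df["weight"].to_numpy(dtype=float) if weighted else np.ones(len(df))
    entry_age = df["entry_age"].to_numpy(dtype=int)
    entry_year = df["entry_year"].to_numpy(dtype=int)
    exit_idx = _exit_intervals(t, event, width)

    intervals = counts["interval"].to_numpy(dtype=int)
    d_star = np.zeros(len(intervals))
    for k, i in enumerate(intervals):
        at_risk = exit_idx >= i
        if not at_risk.any():
            continue
        # attained age/year advance one year per unit of follow-up time
        offset = int(np.floor(i * width))
        q = table.q_values(sid[at_risk], entry_year[at_risk] + offset,
                           entry_age[at_risk] + offset)
        contrib = w[at_risk] * q
        withdrawn_here = (exit_idx[at_risk] == i) & (event[at_risk] == 0)
        contrib = np.where(withdrawn_here, 0.5 * contrib, contrib)
        d_star[k] = contrib.sum()

    l_eff = (counts["L"] - counts["W"] / 2.0).to_numpy(dtype=float)
    p_star = 1.0 - d_star / l_eff
    return pd.DataFrame(
        {
            "interval": intervals,
            "D_star": d_star,
            "P_star": p_star,
            "CP_star": np.cumprod(p_star),
        }
    )


def relative_ratios(observed: pd.DataFrame, expected: pd.DataFrame) -> pd.DataFrame:
    """Elementwise relative survival ``R = P/P*`` and ``CR = CP/CP*`` (no clamping)."""
    merged = observed.merge(expected, on="interval", how="left")
    bad = (merged["P_star"] <= 0) | (merged["CP_star"] <= 0)
    if bad.any():
        i = int(merged.loc[bad, "interval"].iloc[0])
        raise ValueError(f"interval {i}: expected survival is not positive")
    merged["R"] = merged["P"] / merged["P_star"]
    merged["CR"] = merged["CP"] / merged["CP_star"]
    return merged


def cr_confidence_interval(rows: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Greenwood log-scale confidence bounds for cumulative relative survival.

    ``var(log CP(i)) = sum_{k<=i} D_k / (L'_k (L'_k - D_k))`` with the
    expected curve treated as fixed; bounds are
    ``exp(log CR +/- z * sqrt(var))``.
    """
    d = rows["D"].to_numpy(dtype=float)
    l_eff = rows["L_eff"].to_numpy(dtype=float)
    if np.any((l_eff - d) <= 0):
        i = int(rows["interval"].to_numpy()[(l_eff - d) <= 0][0])
        raise ValueError(f"interval {i}: L' equals D, Greenwood variance undefined")
    var = np.cumsum(d / (l_eff * (l_eff - d)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = rows.copy()
    half = z * np.sqrt(var)
    out["ci_low"] = out["CR"] * np.exp(-half)
    out["ci_high"] = out["CR"] * np.exp(half)
    return out


def _coerce_expected(expected, counts: pd.DataFrame) -> pd.DataFrame:
    """Accept an injected expected-survival vector or frame (validation mode).

    An array-like is taken as per-interval ``P*`` with ``CP*`` by cumulative
    product; a mapping/DataFrame may carry ``P_star`` and, optionally, a
    published ``CP_star`` column used as given (avoids compounding the
    rounding of printed interval values).
    """
    n = len(counts)
    if isinstance(expected, (pd.DataFrame, dict)):
        exp_df = pd.DataFrame(expected).reset_index(drop=True)
        if "P_star" not in exp_df.columns:
            raise ValueError("injected expected survival needs a 'P_star' column")
        if len(exp_df) != n:
            raise ValueError(f"expected survival has {len(exp_df)} rows, counts have {n}")
        p_star = exp_df["P_star"].to_numpy(dtype=float)
        cp_star = (
            exp_df["CP_star"].to_numpy(dtype=float)
            if "CP_star" in exp_df.columns
            else np.cumprod(p_star)
        )
    else:
        p_star = np.asarray(expected, dtype=float)
        if p_star.shape != (n,):
            raise ValueError(f"expected P* vector has length {len(p_star)}, need {n}")
        cp_star = np.cumprod(p_star)
    l_eff = (counts["L"] - counts["W"] / 2.0).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "interval": counts["interval"].to_numpy(),
            "D_star": (1.0 - p_star) * l_eff,
            "P_star": p_star,
            "CP_star": cp_star,
        }
    )


def run_life_table(
    records=None,
    *,
    counts: pd.DataFrame | None = None,
    table: PopulationLifeTable | None = None,
    expected=None,
    width: float = 1.0,
    weighted: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """Full life-table stage: tabulate, observed, expected, ratios, intervals.

    Either ``records`` (individual data) or pre-tabulated ``counts`` must be
    given.  Expected survival comes from Ederer II against ``table`` when
    individual records are available, or from an injected ``expected``
    vector/frame (validation mode with published columns).
    """
    if counts is None:
        if records is None:
            raise ValueError("need records or pre-tabulated counts")
        counts = tabulate_intervals(records, width=width, weighted=weighted)
    obs = observed_survival(counts)
    if expected is not None:
        exp_df = _coerce_expected(expected, obs)
    else:
        if records is None or table is None:
            raise ValueError("Ederer II expected survival needs records and a life table")
        exp_df = ederer2_expected(records, table, obs, width=width, weighted=weighted)
    rows = relative_ratios(obs, exp_df)
    rows = cr_confidence_interval(rows, level=level)
    return rows[TABLE_COLUMNS].reset_index(drop=True)


def run_life_table_by(
    records, by: str, table: PopulationLifeTable | None = None, **kwargs
) -> dict[str, pd.DataFrame]:
    """Re-run the life-table stage within each level of a grouping column."""
    df = cohort_frame(records)
    if by not in df.columns:
        raise KeyError(f"grouping column {by!r} not in cohort")
    return {
        str(level): run_life_table(grp, table=table, **kwargs)
        for level, grp in df.groupby(by, sort=True)
    }


def subgroup_summary(
    records, by: str | Iterable[str], table: PopulationLifeTable, **kwargs
) -> pd.DataFrame:
    """End-of-follow-up cumulative relative survival per subgroup.

    One row per level of each grouping column with ``CR`` and its confidence
    bounds at the final interval — the usual one-line-per-subgroup summary
    of a stratified relative-survival analysis.
    """
    groups = [by] if isinstance(by, str) else list(by)
    rows = []
    for col in groups:
        for level, run in run_life_table_by(records, col, table=table, **kwargs).items():
            last = run.iloc[-1]
            rows.append(
                {
                    "group": col,
                    "level": level,
                    "intervals": len(run),
                    "CR": last["CR"],
                    "ci_low": last["ci_low"],
                    "ci_high": last["ci_high"],
                }
            )
    return pd.DataFrame(rows)
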