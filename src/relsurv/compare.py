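"""Cohort-vs-reference-survey comparison and counterfactual reweighting.

Two ways of asking how a volunteer cohort differs from the population it was
drawn from: a Pearson chi-square test of each baseline characteristic's
category distribution against a contemporaneous reference survey, and a
direct standardisation that answers "what would the cohort's cumulative
mortality have been if its category mix matched the reference survey?" —
the counterfactual that quantifies how much of a healthy-volunteer survival
advantage a single characteristic can explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CategoryTable, cohort_frame
from .lifetables import PopulationLifeTable
from .relative import run_life_table

logger = logging.getLogger(__name__)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_compare(table: CategoryTable, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the k x 2 cohort-vs-reference count table.

    Requires counts on both sides (percentages must first go through
    :func:`reconstruct_counts`); no continuity correction by default.
    """
    obs = np.column_stack([table.cohort_counts, table.reference_counts])
    sums = obs.sum(axis=0)
    if all(abs(s - 100.0) < 0.5 for s in sums) and np.any(obs != np.round(obs)):
        raise ValueError(
            f"{table.covariate}: both columns sum to ~100 — these look like "
            "percentages; reconstruct counts with reconstruct_counts(pct, total_n)"
        )
    expected = np.outer(obs.sum(axis=1), sums) / obs.sum()
    if np.any(expected <= 0):
        raise ValueError(f"{table.covariate}: zero expected cell count")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def reconstruct_counts(
    percentages, total_n: int, force_total: bool = False
) -> np.ndarray:
    """Recover category counts from published percentages and a total.

    ``counts = round(pct/100 * N)``.  Printed percentages carry rounding, so
    the percentages must sum to 100 within +/-0.5 and the reconstructed
    counts may miss ``N`` slightly (logged).  With ``force_total`` the counts
    are repaired to sum exactly to ``N`` by largest remainder.
    """
    pct = np.asarray(percentages, dtype=float)
    if abs(pct.sum() - 100.0) > 0.5:
        raise ValueError(f"percentages sum to {pct.sum():.2f}, outside 100 +/- 0.5")
    raw = pct / 100.0 * total_n
    counts = np.round(raw).astype(int)
    gap = total_n - counts.sum()
    if gap != 0:
        logger.info("reconstructed counts sum to %d, total is %d", counts.sum(), total_n)
        if force_total:
            order = np.argsort(-(raw - np.floor(raw)) * np.sign(gap))
            for j in range(abs(int(gap))):
                counts[order[j % len(counts)]] += int(np.sign(gap))
    return counts


@dataclass
class ReweightResult:
    """Observed and counterfactually reweighted cumulative mortality."""

    mortality_observed: float
    mortality_reweighted: float
    ratio: float
    per_category: pd.DataFrame


def counterfactual_reweight(
    records,
    covariate: str,
    target_dist: dict[str, float],
    horizon: float,
    table: PopulationLifeTable,
    width: float = 1.0,
    weighted: bool = True,
) -> ReweightResult:
    """Direct standardisation of cumulative mortality to a target category mix.

    Per category ``k`` of ``covariate``, the life-table stage is run within
    the category and ``M_k = 1 - CP_k(horizon)`` taken as its cumulative
    mortality.  The observed mortality mixes the ``M_k`` with the cohort's
    (weighted) category proportions, the counterfactual with the target
    proportions; the ratio says by how much cumulative mortality would
    change if the cohort had the target's composition.
    """
    df = cohort_frame(records)
    if covariate not in df.columns:
        raise KeyError(f"covariate {covariate!r} not in cohort")
    target = {str(k): float(v) for k, v in target_dist.items()}
    if abs(sum(target.values()) - 1.0) > 1e-6:
        raise ValueError(f"target proportions sum to {sum(target.values())}, not 1")
    present = set(map(str, df[covariate].unique()))
    missing = sorted(set(target) - present)
    if missing:
        raise ValueError(f"target categories absent from cohort: {missing}")
    if horizon > df["follow_up"].max() + width:
        raise ValueError(
            f"horizon {horizon} exceeds the longest follow-up {df['follow_up'].max()}"
        )

    w = df["weight"].to_numpy(dtype=float) if weighted else np.ones(len(df))
    n_int = int(np.ceil(horizon / width - 1e-9))
    rows = []
    for cat in target:
        sub = df[df[covariate].astype(str) == cat]
        if len(sub) == 0 or sub["weight"].sum() <= 0:
            raise ValueError(f"category {cat!r} has no at-risk records")
        run = run_life_table(sub, table=table, width=width, weighted=weighted)
        if len(run) < n_int:
            raise ValueError(
                f"category {cat!r}: follow-up ends before the {horizon}-year horizon"
            )
        cp = float(run["CP"].iloc[n_int - 1])
        wsub = sub["weight"].to_numpy(dtype=float) if weighted else np.ones(len(sub))
        rows.append({"category": cat, "proportion_observed": wsub.sum() / w.sum(),
                     "proportion_target": target[cat], "cumulative_mortality": 1.0 - cp})
    per = pd.DataFrame(rows)
    m_obs = float((per["proportion_observed"] * per["cumulative_mortality"]).sum()
                  / per["proportion_observed"].sum())
    m_rw = float((per["proportion_target"] * per["cumulative_mortality"]).sum())
    return ReweightResult(
        mortality_observed=m_obs,
        mortality_reweighted=m_rw,
        ratio=m_rw / m_obs,
        per_category=per,
    )
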