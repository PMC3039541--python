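"""Multiplicative relative-mortality (SMR-type) regression on split person-time.

The model scales a fully known population hazard by a log-linear function of
baseline covariates:

    lambda_i(a, s) = lambda*_i(a, s) * exp(beta' z_i)

where ``lambda*`` is the expected hazard from the population life table at
the individual's attained age ``a``, calendar year and stratum ``s``.  A
hazard ratio ``exp(beta) < 1`` means mortality below — i.e. survival better
than — the matched general population.  An intercept is included by default:
it absorbs the cohort-wide log standardised mortality ratio of the reference
group, so the reported hazard ratios are contrasts between covariate levels
(in the one-binary-covariate case the fitted HR is exactly the ratio of the
two groups' SMRs).

Follow-up is split into annual cells at attained-age boundaries (a Lexis
expansion); with the baseline hazard known, the likelihood over cells

    l(beta) = sum w * [ d * (log mu* + beta'z) - mu* * exposure * e^{beta'z} ]

is exactly a Poisson likelihood with offset ``log(mu* * exposure)``, and is
maximised by Newton–Raphson with analytic gradient and Hessian plus
step-halving.  Sampling weights enter as pseudo-likelihood multipliers; the
default covariance is the inverse observed information, with an optional
record-clustered sandwich.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import cohort_frame
from .lifetables import PopulationLifeTable

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"


def split_person_time(
    records, table: PopulationLifeTable, width: float = 1.0
) -> pd.DataFrame:
    """Split each record into annual person-time cells with expected hazards.

    Each record yields ``ceil(follow_up / width)`` cells; exposures sum to
    the follow-up time, the final cell carries the event flag, and ``mu_star``
    is the life-table expected hazard at the cell's attained age, attained
    calendar year and stratum.  Zero-length censored records are dropped with
    a warning; a death with zero follow-up has no defined likelihood
    contribution and is an error.
    """
    df = cohort_frame(records)
    zero = df["follow_up"] <= 0
    if (zero & (df["event"] == 1)).any():
        i = (zero & (df["event"] == 1)).idxmax()
        raise ValueError(f"death with zero follow-up at row {i}: likelihood undefined")
    if zero.any():
        logger.warning("dropping %d record(s) with zero follow-up and no event", zero.sum())
        df = df[~zero].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no usable records after dropping zero follow-up")

    t = df["follow_up"].to_numpy(dtype=float)
    n_cells = np.maximum(np.ceil(t / width - 1e-12).astype(int), 1)
    rec_idx = np.repeat(np.arange(len(df)), n_cells)
    # cell number within each record: 0..n_cells-1
    cell_no = np.arange(len(rec_idx)) - np.repeat(
        np.concatenate(([0], np.cumsum(n_cells)[:-1])), n_cells
    )
    is_last = cell_no == (n_cells[rec_idx] - 1)
    exposure = np.where(is_last, t[rec_idx] - cell_no * width, width)
    event = np.where(is_last, df["event"].to_numpy()[rec_idx], 0)

    year_off = np.floor(cell_no * width).astype(int)
    attained_age = df["entry_age"].to_numpy()[rec_idx] + year_off
    attained_year = df["entry_year"].to_numpy()[rec_idx] + year_off
    sid = np.array([table.stratum_id(s) for s in df["stratum"]])[rec_idx]
    mu_star = table.hazard_values(sid, attained_year, attained_age)

    out = pd.DataFrame(
        {
            "id": df["id"].to_numpy()[rec_idx],
            "cell": cell_no,
            "attained_age": attained_age,
            "attained_year": attained_year,
            "stratum": df["stratum"].to_numpy()[rec_idx],
            "exposure": exposure,
            "event": event,
            "mu_star": mu_star,
            "weight": df["weight"].to_numpy()[rec_idx],
        }
    )
    for c in df.columns:
        if c not in out.columns and c not in ("entry_age", "entry_year", "follow_up"):
            out[c] = df[c].to_numpy()[rec_idx]
    return out


@dataclass
class RegressionFit:
    """Fitted multiplicative relative-mortality model."""

    params: pd.Series
    covariance: pd.DataFrame
    terms: list[tuple[str, str, bool]]  # (covariate, level, is_reference)
    log_likelihood: float
    n_events: float
    n_cells: int
    converged: bool
    n_iter: int
    loglik_path: list[float] = field(default_factory=list)

    def hazard_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Hazard ratios with Wald confidence limits, one row per coefficient."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = pd.Series(np.sqrt(np.diag(self.covariance)), index=self.params.index)
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": se,
                "hazard_ratio": np.exp(self.params),
                "ci_low": np.exp(self.params - z * se),
                "ci_high": np.exp(self.params + z * se),
            }
        )


def _design_matrix(cells: pd.DataFrame, covariates, ref_levels, intercept):
    ref_levels = dict(ref_levels or {})
    cols, names, terms = [], [], []
    if intercept:
        cols.append(np.ones(len(cells)))
        names.append(INTERCEPT)
    for cov in covariates:
        if cov not in cells.columns:
            raise KeyError(f"covariate {cov!r} not present in person-time cells")
        col = cells[cov]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [str(x) for x in col.cat.categories]
        else:
            levels = sorted(map(str, col.dropna().unique()))
        ref = str(ref_levels.get(cov, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of {cov!r}")
        values = col.astype(str).to_numpy()
        terms.append((cov, ref, True))
        for lv in levels:
            if lv == ref:
                continue
            cols.append((values == lv).astype(float))
            names.append(f"{cov}[{lv}]")
            terms.append((cov, lv, False))
    if not cols:
        raise ValueError("empty design: no intercept and no covariates")
    return np.column_stack(cols), names, terms


def fit_multiplicative(
    cells: pd.DataFrame,
    covariates=(),
    ref_levels: dict[str, str] | None = None,
    use_weights: bool = True,
    intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> RegressionFit:
    """Maximum-likelihood fit of ``lambda = lambda* exp(beta'z)``.

    Newton–Raphson with analytic gradient/Hessian, step-halving when a step
    would decrease the likelihood, initialised at ``beta = 0``.  Convergence:
    relative log-likelihood change below ``tol``.  Non-convergence returns a
    flagged fit rather than raising; a rank-deficient design raises naming
    the aliased columns.
    """
    d = cells["event"].to_numpy(dtype=float)
    expo = cells["exposure"].to_numpy(dtype=float)
    mu = cells["mu_star"].to_numpy(dtype=float)
    w = cells["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(cells))
    if (d > 0).sum() == 0:
        raise ValueError("no events: likelihood has no interior maximum")
    if np.any((mu <= 0) & (d > 0)):
        raise ValueError("cell with zero expected hazard but an observed event")
    keep = (mu > 0) & (expo > 0)
    if not keep.all():
        logger.warning("dropping %d cell(s) with zero expected hazard or exposure",
                       (~keep).sum())
    X, names, terms = _design_matrix(cells, covariates, ref_levels, intercept)
    X, d, expo, mu, w = X[keep], d[keep], expo[keep], mu[keep], w[keep]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in np.nonzero(np.abs(np.diag(r)) < 1e-8)[0]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    offset = np.log(mu * expo)
    beta = np.zeros(X.shape[1])

    def loglik(b):
        eta = offset + X @ b
        return float(np.sum(w * (d * eta - np.exp(eta))))

    ll = loglik(beta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = np.exp(offset + X @ beta)
        grad = X.T @ (w * (d - lam))
        hess = (X * (w * lam)[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian at iteration %d", it)
            break
        new_ll = loglik(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_ll = loglik(beta + step)
            halvings += 1
        beta = beta + step
        path.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        logger.warning("relative-mortality fit did not converge in %d iterations", it)

    lam = np.exp(offset + X @ beta)
    info = (X * (w * lam)[:, None]).T @ X
    cov = np.linalg.inv(info)
    return RegressionFit(
        params=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        terms=terms,
        log_likelihood=ll,
        n_events=float((w * d).sum()),
        n_cells=int(keep.sum()),
        converged=converged,
        n_iter=it,
        loglik_path=path,
    )


def robust_covariance(fit: RegressionFit, cells: pd.DataFrame, covariates=(),
                      ref_levels=None, use_weights: bool = True,
                      intercept: bool = True) -> pd.DataFrame:
    """Record-clustered sandwich covariance for a fitted model (optional)."""
    X, names, _ = _design_matrix(cells, covariates, ref_levels, intercept)
    d = cells["event"].to_numpy(dtype=float)
    expo = cells["exposure"].to_numpy(dtype=float)
    mu = cells["mu_star"].to_numpy(dtype=float)
    w = cells["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(cells))
    keep = (mu > 0) & (expo > 0)
    X, d, expo, mu, w = X[keep], d[keep], expo[keep], mu[keep], w[keep]
    ids = cells.loc[keep, "id"].to_numpy()
    beta = fit.params.reindex(names).to_numpy()
    lam = np.exp(np.log(mu * expo) + X @ beta)
    scores = X * (w * (d - lam))[:, None]
    grouped = pd.DataFrame(scores).groupby(ids).sum().to_numpy()
    bread = np.linalg.inv((X * (w * lam)[:, None]).T @ X)
    meat = grouped.T @ grouped
    return pd.DataFrame(bread @ meat @ bread, index=names, columns=names)


def hazard_ratio_table(fit: RegressionFit, level: float = 0.95) -> pd.DataFrame:
    """Publication-shaped hazard-ratio table.

    One row per covariate level in declared order; reference levels show a
    hazard ratio of 1.00 with blank confidence limits; the intercept (the
    reference-group SMR) is omitted.
    """
    if not fit.converged:
        raise ValueError("refusing to format a non-converged fit")
    hr = fit.hazard_ratios(level=level)
    rows = []
    for cov, lv, is_ref in fit.terms:
        if is_ref:
            rows.append({"covariate": cov, "level": lv, "hazard_ratio": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "beta": 0.0, "se": np.nan})
        else:
            r = hr.loc[f"{cov}[{lv}]"]
            rows.append({"covariate": cov, "level": lv,
                         "hazard_ratio": r["hazard_ratio"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "beta": r["beta"], "se": r["se"]})
    return pd.DataFrame(rows)
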