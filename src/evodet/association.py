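"""Grouped Spearman partial correlations between variables and constraint.

For each predictor, its association with a constraint response (dN-like or
phyloP-like) is measured as a Spearman partial correlation controlling for
every variable *outside* the predictor's own variable group — within-group
covariates would absorb the very signal being measured.  All columns are
rank-transformed (average ranks for ties); the partial correlation is the
Pearson correlation of the residuals after projecting ranked x and ranked y
on the ranked covariates plus an intercept, with a t-test p-value on
n - 2 - k degrees of freedom.  Bonferroni correction is applied per response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import CATEGORICAL, FeatureTable


class AssociationError(ValueError):
    pass


@dataclass
class PartialCorrelationRecord:
    variable: str
    group: str
    response: str
    rho: float
    p_value: float
    p_adjusted: float
    n_used: int
    covariate_count: int
    significant: bool


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after least-squares projection on [1, Z]."""
    design = np.column_stack([np.ones(len(M)), Z]) if Z.size else np.ones((len(M), 1))
    beta, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


def spearman_partial(x, y, Z=None) -> tuple[float, float, int]:
    """Spearman partial correlation of x and y given covariate matrix Z.

    Complete cases only; with an empty Z this reduces to the ordinary
    Spearman rank correlation (with its t-distribution p-value).  Returns
    (rho, p_value, n_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None:
        Z = np.empty((len(x), 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    n = int(mask.sum())
    if n < k + 3:
        raise AssociationError(f"only {n} complete rows for {k} covariates; need >= {k + 3}")
    xr, yr = _rank(x[mask]), _rank(y[mask])
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise AssociationError("x or y is constant after ranking")
    Zr = np.column_stack([_rank(Z[mask, j]) for j in range(k)]) if k else np.empty((n, 0))
    res = _residualize(np.column_stack([xr, yr]), Zr)
    rx, ry = res[:, 0], res[:, 1]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise AssociationError("x or y fully explained by the covariates")
    rho = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p, n


def grouped_partial_correlations(
    table: FeatureTable, response: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Partial correlation of every variable with ``response``, other groups as covariates.

    The Bonferroni family is the set of variables tested for this response
    (p_adjusted = min(1, m * p)); a record is significant when
    p_adjusted < ``alpha``.  With a single variable group, covariate sets are
    empty and the statistics are ordinary Spearman correlations.
    """
    if response not in table.responses.columns:
        raise AssociationError(f"unknown response {response!r}")
    variables = [v for v in table.variable_names if table.variable_kind[v] != CATEGORICAL]
    if not variables:
        raise AssociationError("no numeric variables to test")
    groups = {v: table.variable_group[v] for v in variables}
    distinct_groups = sorted(set(groups.values()))
    y = table.responses[response].to_numpy(dtype=float)
    X = table.values[variables].to_numpy(dtype=float)
    col_of = {v: j for j, v in enumerate(variables)}

    if len(distinct_groups) == 1 and len(set(table.variable_group.values())) > 1:
        raise AssociationError(
            f"group {distinct_groups[0]!r} contains every testable variable; "
            "empty covariate sets are only allowed when a single group exists"
        )

    complete = not np.isnan(X).any() and not np.isnan(y).any()
    m = len(variables)
    records: list[PartialCorrelationRecord] = []
    if complete:
        # shared fast path: rank once, residualize each group's members and the
        # response against the other-group covariate block in one projection
        ranks = np.column_stack([_rank(X[:, j]) for j in range(X.shape[1])])
        y_rank = _rank(y)
        n = len(y)
        for g in distinct_groups:
            members = [v for v in variables if groups[v] == g]
            cov_idx = [col_of[v] for v in variables if groups[v] != g]
            Zr = ranks[:, cov_idx]
            res = _residualize(np.column_stack([y_rank] + [ranks[:, col_of[v]] for v in members]), Zr)
            ry = res[:, 0]
            ny = np.linalg.norm(ry)
            for i, v in enumerate(members):
                rx = res[:, 1 + i]
                nx = np.linalg.norm(rx)
                if nx == 0 or ny == 0:
                    raise AssociationError(f"variable {v!r} or response constant after projection")
                rho = float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))
                k = len(cov_idx)
                df = n - 2 - k
                if abs(rho) >= 1.0:
                    p = 0.0
                else:
                    t = rho * np.sqrt(df / (1.0 - rho**2))
                    p = float(2.0 * stats.t.sf(abs(t), df))
                records.append(_record(v, g, response, rho, p, n, k, m, alpha))
    else:
        for v in variables:
            g = groups[v]
            cov = [u for u in variables if groups[u] != g]
            rho, p, n = spearman_partial(
                X[:, col_of[v]], y, X[:, [col_of[u] for u in cov]]
            )
            records.append(_record(v, g, response, rho, p, n, len(cov), m, alpha))

    return pd.DataFrame([r.__dict__ for r in records])


def _record(v, g, response, rho, p, n, k, m, alpha) -> PartialCorrelationRecord:
    p_adj = min(1.0, m * p)
    return PartialCorrelationRecord(
        variable=v,
        group=g,
        response=response,
        rho=rho,
        p_value=p,
        p_adjusted=p_adj,
        n_used=n,
        covariate_count=k,
        significant=bool(p_adj < alpha),
    )


def write_partial_correlations(df: pd.DataFrame, path) -> None:
    out = df.rename(
        columns={"p_value": "p", "p_adjusted": "p_adj", "n_used": "n"}
    )[["variable", "group", "response", "rho", "p", "p_adj", "n", "significant"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
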