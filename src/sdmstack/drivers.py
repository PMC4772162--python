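"""Environmental drivers of richness: trend surface, variation
partitioning, forward stepwise regression, and Moran's I residual
diagnostics.

The spatial signal in richness is described by the nine-term cubic trend
surface of cell coordinates (LON, LAT, LON^2, LON*LAT, LAT^2, LON^3,
LON^2*LAT, LON*LAT^2, LAT^3). Variation partitioning splits the adjusted
R^2 of richness between the environmental block E and the spatial block S
into pure and shared fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .core import EnvMatrix, GridDomain

logger = logging.getLogger(__name__)

__all__ = ["trend_surface_terms", "variation_partition",
           "stepwise_regression", "morans_i", "RichnessModel",
           "MoranResult", "adjusted_r2"]

TREND_TERMS = ["LON", "LAT", "LON2", "LONxLAT", "LAT2", "LON3", "LON2xLAT",
               "LONxLAT2", "LAT3"]


def trend_surface_terms(grid: GridDomain) -> pd.DataFrame:
    """Nine-column cubic trend surface of centered, range-scaled coordinates.

    Coordinates are centered on their mean and scaled to unit range before
    taking powers, which keeps the cubic design well-conditioned without
    changing any partition fraction (affine invariance).
    """
    lon = grid.lon_center
    lat = grid.lat_center
    if np.unique(lon).size < 2 or np.unique(lat).size < 2:
        raise ValueError("grid must have at least 2 distinct lon and lat values")
    x = (lon - lon.mean()) / np.ptp(lon)
    y = (lat - lat.mean()) / np.ptp(lat)
    cols = [x, y, x ** 2, x * y, y ** 2, x ** 3, x ** 2 * y, x * y ** 2, y ** 3]
    return pd.DataFrame(dict(zip(TREND_TERMS, cols)), index=grid.cell_ids)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept; returns (coef, residuals, rank, df_model)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    return coef, resid, rank, rank - 1


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R^2 of an OLS fit of y on X (with intercept).

    Rank-deficient designs use the effective rank as the parameter count,
    so duplicated columns do not inflate the penalty.
    """
    y = np.asarray(y, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("response is constant")
    _, resid, rank, df_model = _ols(y, np.asarray(X, dtype=float))
    n = y.size
    r2 = 1.0 - (resid ** 2).sum() / sst
    if n - df_model - 1 <= 0:
        raise ValueError("not enough observations for the design")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - df_model - 1)


def variation_partition(richness, env: EnvMatrix,
                        space: pd.DataFrame) -> dict[str, float]:
    """Partition adjusted R^2 of richness into environment/space fractions.

    Fits the environmental block E, the spatial block S, and their union,
    and reports pure_env = R2a(E+S) - R2a(S), pure_space = R2a(E+S) -
    R2a(E), shared = R2a(E) + R2a(S) - R2a(E+S), unexplained = 1 -
    R2a(E+S), plus the three block R2a values. Slightly negative fractions
    (an adjusted-R^2 artifact) are reported as-is.
    """
    y = np.asarray(richness, dtype=float)
    E = env.values
    S = space.to_numpy()
    if y.size <= E.shape[1] + S.shape[1] + 1:
        raise ValueError("too few cells for the combined design")
    r2_e = adjusted_r2(y, E)
    r2_s = adjusted_r2(y, S)
    r2_es = adjusted_r2(y, np.column_stack([E, S]))
    return {
        "r2_env": r2_e, "r2_space": r2_s, "r2_combined": r2_es,
        "pure_env": r2_es - r2_s,
        "pure_space": r2_es - r2_e,
        "shared": r2_e + r2_s - r2_es,
        "unexplained": 1.0 - r2_es,
    }


@dataclass
class RichnessModel:
    """Forward-stepwise regression summary (entry order preserved)."""

    steps: pd.DataFrame  # index predictor (entry order); cumulative_r2adj
    betas: pd.Series  # final-model standardized coefficients
    t_values: pd.Series  # final-model t statistics
    r2adj: float


def stepwise_regression(richness, env: EnvMatrix,
                        alpha_enter: float = 0.05) -> RichnessModel:
    """Forward selection of standardized environmental predictors.

    Predictors are z-scored internally so coefficients are betas. At each
    step the candidate with the largest cumulative-adjusted-R^2 gain whose
    partial-F p-value is below ``alpha_enter`` is entered; selection stops
    when no candidate qualifies. The reported t-values are final-model
    statistics.
    """
    y = np.asarray(richness, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("richness is constant")
    Z = env.values.copy()
    sd = Z.std(axis=0)
    usable = sd > 0
    Z = (Z[:, usable] - Z[:, usable].mean(axis=0)) / sd[usable]
    names = [n for n, u in zip(env.names, usable) if u]
    n = y.size
    selected: list[int] = []
    steps = []
    sst = ((y - y.mean()) ** 2).sum()
    sse_cur = sst
    while True:
        best = None
        for j in range(len(names)):
            if j in selected:
                continue
            X = Z[:, selected + [j]]
            _, resid, rank, df_model = _ols(y, X)
            if rank < len(selected) + 2:  # candidate adds nothing (collinear)
                continue
            sse = (resid ** 2).sum()
            df_err = n - df_model - 1
            if df_err <= 0 or sse <= 0:
                continue
            f = (sse_cur - sse) / (sse / df_err)
            p = stats.f.sf(f, 1, df_err)
            r2a = 1.0 - (sse / sst) * (n - 1) / df_err
            if p < alpha_enter and (best is None or r2a > best[1]):
                best = (j, r2a, sse)
        if best is None:
            break
        j, r2a, sse = best
        selected.append(j)
        sse_cur = sse
        steps.append((names[j], r2a))
    if not selected:
        logger.warning("no predictor qualified at alpha_enter=%g", alpha_enter)
        empty = pd.Series(dtype=float)
        return RichnessModel(
            steps=pd.DataFrame(columns=["cumulative_r2adj"]),
            betas=empty, t_values=empty, r2adj=0.0)
    X = Z[:, selected]
    Xd = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    df_err = n - X.shape[1] - 1
    sigma2 = (resid ** 2).sum() / df_err
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))[1:]
    sel_names = [names[j] for j in selected]
    steps_df = pd.DataFrame({"cumulative_r2adj": [s[1] for s in steps]},
                            index=[s[0] for s in steps])
    return RichnessModel(
        steps=steps_df,
        betas=pd.Series(coef[1:], index=sel_names),
        t_values=pd.Series(coef[1:] / se, index=sel_names),
        r2adj=steps[-1][1])


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float


def rook_weights(grid: GridDomain, row_standardize: bool = True) -> sparse.csr_matrix:
    """Rook-contiguity spatial weights over the inside cells."""
    rows_idx = grid.cell_rows
    cols_idx = grid.cell_cols
    pos = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows_idx, cols_idx))}
    ii, jj = [], []
    for i, (r, c) in enumerate(zip(rows_idx, cols_idx)):
        for dr, dc in ((0, 1), (1, 0)):
            nb = pos.get((int(r) + dr, int(c) + dc))
            if nb is not None:
                ii.extend([i, nb])
                jj.extend([nb, i])
    W = sparse.csr_matrix((np.ones(len(ii)), (ii, jj)),
                          shape=(grid.n_cells, grid.n_cells))
    if row_standardize:
        rs = np.asarray(W.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        W = sparse.diags(1.0 / rs) @ W
    return W


def morans_i(values, grid: GridDomain, weights: sparse.spmatrix | None = None,
             ) -> MoranResult:
    """Moran's I with row-standardized rook weights.

    Uses the normal approximation (normality assumption) for the z score
    and two-sided p; the expected value under no autocorrelation is
    -1/(n-1). Constant inputs are undefined and raise.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    W = rook_weights(grid) if weights is None else weights.tocsr()
    n = x.size
    z = x - x.mean()
    s0 = W.sum()
    num = z @ (W @ z)
    I = (n / s0) * num / (z @ z)
    e_i = -1.0 / (n - 1)
    Wd = W.toarray()
    s1 = 0.5 * ((Wd + Wd.T) ** 2).sum()
    s2 = ((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i ** 2
    zscore = (I - e_i) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=float(e_i), z=float(zscore),
                       p=float(p))
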