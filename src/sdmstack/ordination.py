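"""Relative environmental turnover: NMDS, vector fitting, Getis-Ord Gi*.

Non-metric multidimensional scaling embeds the beta-sim matrix in two
dimensions by minimizing Kruskal stress-1 (0 = perfect rank agreement, 1 =
none). Environmental vectors are fitted to the ordination by least squares
with permutation p-values, and each region's environmental distinctness is
summarized by the Getis-Ord Gi* z-statistic against the whole domain, with
|z| > 2 flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .core import EnvMatrix, GridDomain
from .regionalize import DissimMatrix, Regionalization

logger = logging.getLogger(__name__)

__all__ = ["nmds", "envfit", "gi_star", "ret_table", "coarsen",
           "OrdinationResult", "EnvfitVectors", "kruskal_stress"]


def kruskal_stress(d_obs: np.ndarray, scores: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Disparities are the isotonic (monotone non-decreasing) regression of
    configuration distances on the observed dissimilarities; stress-1 =
    sqrt(sum (dist - disparity)^2 / sum dist^2).
    """
    from sklearn.isotonic import IsotonicRegression

    do = squareform(d_obs, checks=False)
    dc = pdist(scores)
    order = np.argsort(do, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(dc)
    disp[order] = iso.fit_transform(np.arange(order.size), dc[order])
    denom = (dc ** 2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((dc - disp) ** 2).sum() / denom))


@dataclass
class OrdinationResult:
    scores: np.ndarray  # (n, n_dims), centered, principal-axis rotated
    stress: float
    n_starts: int
    best_start: int
    start_stress: np.ndarray
    cell_ids: np.ndarray | None = None


def _classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson double-centering embedding used to seed the first start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_dims]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(d: DissimMatrix | np.ndarray, n_dims: int = 2, n_starts: int = 100,
         seed: int = 0, max_iter: int = 500, eps: float = 1e-6,
         ) -> OrdinationResult:
    """Best-of-``n_starts`` non-metric MDS under Kruskal stress-1.

    The first start is initialized from the classical (Torgerson) metric
    embedding — which already solves exactly embeddable inputs — and the
    remaining starts are seeded random configurations. The best solution
    is centered and rotated to its principal axes.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if isinstance(d, DissimMatrix):
        D, cell_ids = d.values, d.cell_ids
    else:
        D, cell_ids = np.asarray(d, dtype=float), None
    rng = np.random.default_rng(seed)
    best_scores, stresses = None, []
    for start in range(n_starts):
        init = (_classical_mds(D, n_dims) if start == 0
                else rng.standard_normal((D.shape[0], n_dims)))
        scores, _, _ = smacof(
            D, metric=False, n_components=n_dims, init=init, n_init=1,
            max_iter=max_iter, eps=eps, random_state=0,
            normalized_stress=True, return_n_iter=True)
        stresses.append(kruskal_stress(D, scores))
        if best_scores is None or stresses[-1] < min(stresses[:-1]):
            best_scores = scores
    stresses = np.asarray(stresses)
    best = int(stresses.argmin())
    scores = best_scores - best_scores.mean(axis=0)
    # rotate to principal axes for a reproducible orientation
    _, _, vt = np.linalg.svd(scores, full_matrices=False)
    scores = scores @ vt.T
    return OrdinationResult(scores=scores, stress=float(stresses[best]),
                            n_starts=n_starts, best_start=best,
                            start_stress=stresses, cell_ids=cell_ids)


@dataclass
class EnvfitVectors:
    """Fitted environmental vectors on an ordination."""

    table: pd.DataFrame  # index predictor; cos1, cos2, r2, p, significant
    alpha: float
    n_perm: int


def envfit(ord_result: OrdinationResult, env: EnvMatrix, n_perm: int = 999,
           alpha: float = 0.001, seed: int = 0) -> EnvfitVectors:
    """Least-squares environmental vectors with permutation significance.

    Each (standardized) predictor is regressed on the ordination axes;
    r^2 is the fraction of its variance explained and the direction is the
    unit coefficient vector. The p-value permutes the predictor's rows:
    p = (1 + #{permuted r^2 >= observed}) / (n_perm + 1). ``env`` rows
    must align with the ordination rows.
    """
    X = ord_result.scores
    n = X.shape[0]
    if env.n_cells != n:
        raise ValueError("env rows must align with ordination rows")
    Xd = np.column_stack([np.ones(n), X])
    pinv = np.linalg.pinv(Xd)
    hat = Xd @ pinv

    def r2_of(y: np.ndarray) -> tuple[float, np.ndarray]:
        yc = y - y.mean()
        sst = (yc ** 2).sum()
        fitted = hat @ y
        ssr = ((fitted - fitted.mean()) ** 2).sum()
        coef = (pinv @ y)[1:]
        return (ssr / sst if sst > 0 else 0.0), coef

    rng = np.random.default_rng(seed)
    rows = {}
    for name in env.names:
        y = env[name]
        if np.ptp(y) == 0:
            logger.warning("constant predictor %r in envfit", name)
            rows[name] = {"cos1": 0.0, "cos2": 0.0, "r2": 0.0, "p": 1.0,
                          "significant": False}
            continue
        y = (y - y.mean()) / y.std()
        r2, coef = r2_of(y)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        ge = 1
        for _ in range(n_perm):
            r2p, _ = r2_of(rng.permutation(y))
            ge += r2p >= r2
        p = ge / (n_perm + 1)
        rows[name] = {"cos1": float(direction[0]),
                      "cos2": float(direction[1]) if X.shape[1] > 1 else 0.0,
                      "r2": float(r2), "p": float(p),
                      "significant": bool(p < alpha)}
    return EnvfitVectors(pd.DataFrame.from_dict(rows, orient="index"),
                         alpha=alpha, n_perm=n_perm)


def gi_star(values, region_cells, all_cells=None) -> float:
    """Getis-Ord Gi* z-value of a region against the whole domain.

    Binary weights (1 inside the region, 0 outside) with the global mean
    and standard deviation:

        z = (sum_region x - n_r xbar) / (S sqrt[(n n_r - n_r^2) / (n - 1)])

    Its sign equals the sign of the region mean minus the global mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    region = np.asarray(sorted(region_cells), dtype=int)
    n_r = region.size
    if n_r == 0 or n_r >= n:
        raise ValueError("region must be a non-empty strict subset of the domain")
    if np.ptp(x) == 0:
        raise ValueError("Gi* undefined for constant values")
    xbar = x.mean()
    s = np.sqrt((x ** 2).mean() - xbar ** 2)
    num = x[region].sum() - n_r * xbar
    den = s * np.sqrt((n * n_r - n_r ** 2) / (n - 1))
    return float(num / den)


def coarsen(grid: GridDomain, env: EnvMatrix, labels: np.ndarray,
            factor: int = 2) -> tuple[EnvMatrix, np.ndarray]:
    """Aggregate cells into factor x factor blocks.

    Environmental values average within each block; region labels transfer
    by majority vote (ties to the smallest label). ``labels`` must cover
    every inside cell (use -1 for cells without a region).
    """
    if factor < 1:
        raise ValueError("coarsening factor must be >= 1")
    if factor == 1:
        return env, np.asarray(labels).copy()
    block = grid.cell_rows // factor * ((grid.n_lon + factor - 1) // factor) \
        + grid.cell_cols // factor
    order = np.unique(block)
    env_coarse = env.data.groupby(block).mean()
    env_coarse.index = np.arange(len(order))
    lab = np.asarray(labels)
    out_labels = np.empty(len(order), dtype=int)
    for i, b in enumerate(order):
        sub = lab[block == b]
        sub = sub[sub >= 0]
        if sub.size == 0:
            out_labels[i] = -1
        else:
            vals, counts = np.unique(sub, return_counts=True)
            out_labels[i] = int(vals[counts.argmax()])
    return EnvMatrix(env_coarse), out_labels


def ret_table(regionalization: Regionalization, grid: GridDomain,
              env: EnvMatrix, coarsen_factor: int = 2,
              z_threshold: float = 2.0) -> pd.DataFrame:
    """Per-region Gi* for every predictor on a coarsened grid.

    Returns a predictors x regions table of Gi* z-values; the companion
    ``<region>_sig`` columns flag |z| > ``z_threshold``. Regions that
    vanish after coarsening get NaN rows and a warning.
    """
    full_labels = np.full(grid.n_cells, -1, dtype=int)
    full_labels[regionalization.cell_ids] = regionalization.labels
    env_c, lab_c = coarsen(grid, env, full_labels, coarsen_factor)
    regions = np.unique(regionalization.labels)
    out = {}
    sig = {}
    for r in regions:
        cells = np.flatnonzero(lab_c == r)
        col = []
        for name in env_c.names:
            if cells.size == 0 or cells.size >= env_c.n_cells:
                col.append(np.nan)
            else:
                col.append(gi_star(env_c[name], cells))
        if cells.size == 0:
            logger.warning("region %d vanished after coarsening", int(r))
        out[f"region{r}"] = col
        sig[f"region{r}_sig"] = [abs(v) > z_threshold if np.isfinite(v)
                                 else False for v in col]
    table = pd.DataFrame({**out, **sig}, index=env_c.names)
    return table
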