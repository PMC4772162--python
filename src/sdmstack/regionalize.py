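"""Compositional turnover and phytogeographical regionalization.

Pairwise turnover between grid-cell assemblages uses the
richness-independent beta-sim index

    beta_sim = min(b, c) / (min(b, c) + a)

with a the species shared by the two cells and b, c the species unique to
each; 0 means identical lists, 1 means no shared taxa, and a surplus of
species in the richer cell does not change the value. Cells are clustered
by UPGMA (average linkage) on the beta-sim matrix, indicator species
analysis scores how well species mark the clusters, and the number of
regions is chosen by minimizing the summed indicator p-values over a range
of cluster counts on repeated random cell subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stacking import PresenceAbsenceMatrix

logger = logging.getLogger(__name__)

__all__ = ["beta_sim", "dissimilarity_matrix", "upgma", "cut_tree",
           "dendrogram_to_newick", "indval", "optimal_k", "DissimMatrix",
           "Regionalization"]


def beta_sim(set_i, set_j) -> float:
    """beta-sim turnover between two species sets.

    min(b,c)/(min(b,c)+a): 0 for identical lists, 1 for disjoint ones.
    When one cell is empty the pair shares no taxa and the value is 1;
    both cells empty is undefined and raises.
    """
    si, sj = frozenset(set_i), frozenset(set_j)
    if not si and not sj:
        raise ValueError("beta-sim undefined for two empty assemblages")
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    m = min(b, c)
    if m + a == 0:  # one cell empty, no shared taxa
        return 1.0
    return m / (m + a)


@dataclass
class DissimMatrix:
    """Symmetric beta-sim matrix over the retained (non-empty) cells."""

    values: np.ndarray  # (n, n) in [0, 1], zero diagonal
    cell_ids: np.ndarray  # original cell ids of the rows
    excluded_cells: np.ndarray  # empty cells left out

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def dissimilarity_matrix(pa: PresenceAbsenceMatrix, level: str = "species",
                         genus_map: dict[str, str] | None = None,
                         ) -> DissimMatrix:
    """Pairwise beta-sim over all non-empty cells of a stacked matrix.

    ``level='genus'`` aggregates species columns through ``genus_map``
    (a cell has a genus iff it has at least one member species). Cells
    with zero taxa are excluded with a logged census.
    """
    M = pa.pa.to_numpy().astype(np.int64)
    if level == "genus":
        if genus_map is None:
            raise ValueError("genus level requires a genus_map")
        genera = pd.Series([genus_map[s] for s in pa.species])
        M = pd.DataFrame(M, columns=pa.species).T.groupby(
            genera.values).max().T.to_numpy()
    elif level != "species":
        raise ValueError(f"unknown level {level!r}")
    richness = M.sum(axis=1)
    keep = richness > 0
    if (~keep).any():
        logger.info("excluding %d empty cells from the dissimilarity matrix",
                    int((~keep).sum()))
    M = M[keep]
    r = richness[keep].astype(float)
    shared = (M @ M.T).astype(float)  # a
    bu = r[:, None] - shared  # species unique to cell i
    cu = r[None, :] - shared
    m = np.minimum(bu, cu)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = m / (m + shared)
    d[np.isnan(d)] = 0.0  # only when m + a = 0, impossible for non-empty cells
    np.fill_diagonal(d, 0.0)
    return DissimMatrix(values=d,
                        cell_ids=pa.pa.index.to_numpy()[keep],
                        excluded_cells=pa.pa.index.to_numpy()[~keep])


def upgma(d: DissimMatrix | np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration; returns a scipy linkage matrix."""
    values = d.values if isinstance(d, DissimMatrix) else np.asarray(d)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    return hierarchy.linkage(squareform(values, checks=False), method="average")


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels (0..k-1, relabeled by first appearance) at exactly k clusters.

    Cuts by merge order, so tied merge heights (common with saturated
    beta-sim values of exactly 1) still yield exactly k groups.
    """
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    _, out = np.unique(labels, return_inverse=True)
    return out


def dendrogram_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    """Export a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def name(node) -> str:
        if labels is not None:
            return str(labels[node.id])
        return f"t{node.id}"

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{name(node)}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def _indval_scores(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Max-over-clusters Dufrene-Legendre indicator value per species.

    IndVal(species, cluster) = specificity x fidelity x 100, where
    specificity is the cluster's share of the species' mean presence rate
    across clusters and fidelity the fraction of the cluster's cells
    occupied.
    """
    ks = np.unique(labels)
    rates = np.stack([M[labels == k].mean(axis=0) for k in ks])  # (k, n_sp)
    total = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(total > 0, rates / total, 0.0)
    indval = specificity * rates * 100.0  # fidelity == rates for binary data
    return indval.max(axis=0)


def indval(pa_matrix: np.ndarray, labels: np.ndarray, n_perm: int = 1000,
           seed: int = 0) -> pd.DataFrame:
    """Indicator value and Monte-Carlo p per species for a clustering.

    p = (1 + #{permuted IndVal >= observed}) / (n_perm + 1) under random
    relabeling of cells. Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels)
    M = np.asarray(pa_matrix)
    if np.unique(labels).size < 2:
        raise ValueError("indval requires at least 2 clusters")
    obs = _indval_scores(M, labels)
    rng = np.random.default_rng(seed)
    ge = np.ones(M.shape[1])  # the observed ordering counts once
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ge += _indval_scores(M, perm) >= obs
    p = ge / (n_perm + 1)
    return pd.DataFrame({"indval": obs, "p": p})


@dataclass
class Regionalization:
    """UPGMA labels at the chosen k plus the model-selection trace."""

    linkage: np.ndarray
    labels: np.ndarray  # per retained cell, 0..k-1
    cell_ids: np.ndarray
    chosen_k: int
    summed_p: pd.DataFrame  # index k; one column per repeat + 'mean'
    excluded_cells: np.ndarray

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels})


def optimal_k(pa: PresenceAbsenceMatrix, k_range=range(2, 31),
              subsample_size: int = 1000, n_repeats: int = 5,
              n_perm: int = 1000, seed: int = 0,
              level: str = "species",
              genus_map: dict[str, str] | None = None,
              criterion: str = "sum_p") -> Regionalization:
    """Choose the number of regions by minimum mean summed indicator p.

    For each repeat a random subsample of cells is clustered by UPGMA; at
    every k in ``k_range`` the subsample tree is cut and the sum of
    per-species indicator p-values recorded. The k minimizing the mean
    curve wins, and the full-matrix dendrogram is cut at that k for the
    final labels.

    ``criterion='n_significant'`` scores each k by the negated count of
    significant indicator species (p < 0.05) instead of the raw p sum, so
    the same argmin rule applies; the default remains the summed p.
    """
    if criterion not in ("sum_p", "n_significant"):
        raise ValueError(f"unknown criterion {criterion!r}")
    dm = dissimilarity_matrix(pa, level=level, genus_map=genus_map)
    k_range = list(k_range)
    subsample_size = min(subsample_size, dm.n)
    if max(k_range) >= subsample_size:
        raise ValueError("k_max must be smaller than the subsample size")
    M_full = pa.pa.loc[dm.cell_ids].to_numpy()
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(n_repeats)
    curves = {}
    for rep in range(n_repeats):
        rng = np.random.default_rng(repeat_seeds[rep])
        idx = np.sort(rng.choice(dm.n, size=subsample_size, replace=False))
        Zs = upgma(dm.values[np.ix_(idx, idx)])
        Ms = M_full[idx]
        occupied = Ms.sum(axis=0) > 0  # species absent from the subsample drop out
        col = []
        for k in k_range:
            labels = cut_tree(Zs, k)
            res = indval(Ms[:, occupied], labels, n_perm=n_perm,
                         seed=int(rng.integers(2 ** 31)))
            if criterion == "sum_p":
                col.append(res["p"].sum())
            else:
                col.append(-float((res["p"] < 0.05).sum()))
        curves[f"repeat{rep}"] = col
    summed = pd.DataFrame(curves, index=pd.Index(k_range, name="k"))
    summed["mean"] = summed.mean(axis=1)
    chosen = int(summed["mean"].idxmin())
    Z_full = upgma(dm)
    labels = cut_tree(Z_full, chosen)
    return Regionalization(linkage=Z_full, labels=labels, cell_ids=dm.cell_ids,
                           chosen_k=chosen, summed_p=summed,
                           excluded_cells=dm.excluded_cells)
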