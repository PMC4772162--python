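"""Collinearity pruning and environmental collection-bias diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EnvMatrix

logger = logging.getLogger(__name__)

__all__ = ["prune_predictors", "bias_test", "BiasReport", "PruneReport"]


@dataclass
class PruneReport:
    """Dropped predictors with the partner and rho that triggered each drop."""

    dropped: pd.DataFrame  # columns: predictor, partner, rho

    def __len__(self) -> int:
        return len(self.dropped)


def prune_predictors(env: EnvMatrix, rho_max: float = 0.75,
                     priority: list[str] | None = None,
                     ) -> tuple[EnvMatrix, PruneReport]:
    """Greedy priority-ordered removal of collinear predictors.

    Predictors are visited in ``priority`` order (the "ecologically most
    meaningful first" ranking, defaulting to column order); each one is
    kept unless its Spearman |rho| with an already-kept predictor reaches
    ``rho_max``, in which case it is dropped and the triggering partner and
    rho recorded. The surviving set therefore has all pairwise
    |rho| < rho_max, and the result does not depend on column order once a
    priority list is fixed.
    """
    if not 0 < rho_max < 1:
        raise ValueError("rho_max must be in (0, 1)")
    if priority is None:
        priority = env.names
    missing = set(env.names) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover predictors: {sorted(missing)}")
    ranks = pd.DataFrame(
        {n: stats.rankdata(env[n]) for n in env.names})
    rho = ranks.corr(method="pearson")  # Spearman = Pearson on ranks
    kept: list[str] = []
    rows = []
    for name in priority:
        if name not in env.data.columns:
            continue
        partner = None
        for k in kept:
            if abs(rho.loc[name, k]) >= rho_max:
                partner = k
                break
        if partner is None:
            kept.append(name)
        else:
            rows.append((name, partner, float(rho.loc[name, partner])))
    report = PruneReport(pd.DataFrame(rows, columns=["predictor", "partner", "rho"]))
    if rows:
        logger.info("pruned %d collinear predictors: %s", len(rows),
                    [r[0] for r in rows])
    return env.subset(kept), report


@dataclass
class BiasReport:
    """Per-predictor chi-square comparison of collection cells vs the domain."""

    table: pd.DataFrame  # index predictor; columns chi2, df, p, biased
    n_bins: int
    n_collection_cells: int
    alpha: float

    @property
    def n_biased(self) -> int:
        return int(self.table["biased"].sum())

    def __repr__(self) -> str:
        return (f"BiasReport({self.n_biased}/{len(self.table)} predictors "
                f"biased at alpha={self.alpha})")


def _binned_counts(x: np.ndarray, coll: np.ndarray, n_bins: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-interval bin counts over the domain and the collection cells.

    Bins span the full domain range; empty domain bins are merged into
    their nearest non-empty neighbour so expected counts are never zero.
    """
    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    # top edge closed so the maximum falls in the last bin
    dom = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    col = np.clip(np.searchsorted(edges, coll, side="right") - 1, 0, n_bins - 1)
    dom_counts = np.bincount(dom, minlength=n_bins).astype(float)
    col_counts = np.bincount(col, minlength=n_bins).astype(float)
    nonempty = np.flatnonzero(dom_counts > 0)
    if nonempty.size < n_bins:
        acc_dom = np.zeros(n_bins)
        acc_col = np.zeros(n_bins)
        for b in range(n_bins):
            target = b if dom_counts[b] > 0 else nonempty[np.abs(nonempty - b).argmin()]
            acc_dom[target] += dom_counts[b]
            acc_col[target] += col_counts[b]
        keep = acc_dom > 0
        return acc_dom[keep], acc_col[keep]
    return dom_counts, col_counts


def bias_test(env: EnvMatrix, collection_cells, n_bins: int = 10,
              alpha: float = 0.05) -> BiasReport:
    """Chi-square test of environmental representativeness of collecting.

    For every predictor, the domain-wide value range is split into
    ``n_bins`` equal-interval bins; expected collection counts follow the
    domain's bin proportions, observed counts come from the collection
    cells. A predictor whose collection localities depart from the domain
    distribution (p < alpha) is flagged biased. Constant predictors are
    untestable and excluded with a warning.

    ``collection_cells`` may contain repeated cells (visit multiplicities
    count), under which the Pearson statistic's multinomial null holds
    exactly; deduplicated cell subsets of a small domain behave mildly
    conservatively (finite-population effect).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    coll = np.asarray(sorted(collection_cells), dtype=int)
    if coll.size == 0:
        raise ValueError("collection_cells is empty")
    if coll.min() < 0 or coll.max() >= env.n_cells:
        raise ValueError("collection_cells outside the domain")
    rows = {}
    for name in env.names:
        x = env[name]
        if np.ptp(x) == 0:
            logger.warning("predictor %r is constant; excluded from bias test", name)
            continue
        dom_counts, col_counts = _binned_counts(x, x[coll], n_bins)
        expected = dom_counts / dom_counts.sum() * coll.size
        chi2 = float(((col_counts - expected) ** 2 / expected).sum())
        df = int(len(dom_counts) - 1)
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        rows[name] = {"chi2": chi2, "df": df, "p": p, "biased": p < alpha}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return BiasReport(table=table, n_bins=n_bins,
                      n_collection_cells=int(coll.size), alpha=alpha)
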