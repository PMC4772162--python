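"""Thresholding continuous suitability and stacking presence/absence.

Continuous model output is converted to presence/absence per species with
a sample-size-dependent rule — ROC-derived thresholds (sensitivity =
specificity, or maximization of their sum) for sparse species with 5-9
records, the fixed 10th-percentile-of-training-presences threshold for
species with 10 or more — and the binary layers are stacked into a cells x
species matrix whose row sums are the species-richness map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import SDMFit

logger = logging.getLogger(__name__)

__all__ = ["choose_threshold", "stack", "PresenceAbsenceMatrix",
           "THRESHOLD_RULES"]

THRESHOLD_RULES = ("sens_spec_equal", "sum_max", "p10")


def _roc_threshold(fit: SDMFit, rule: str) -> float:
    suit = fit.suitability
    pres = np.asarray(sorted(fit.presences), dtype=int)
    pres_sorted = np.sort(suit[pres])
    bg_sorted = np.sort(suit)  # background = all domain cells
    candidates = np.unique(suit)
    # presence calls use suitability >= t
    sens = 1.0 - np.searchsorted(pres_sorted, candidates, side="left") / pres_sorted.size
    spec = np.searchsorted(bg_sorted, candidates, side="left") / bg_sorted.size
    if rule == "sens_spec_equal":
        score = -np.abs(sens - spec)
    else:  # sum_max
        score = sens + spec
    best = np.flatnonzero(score == score.max())[0]  # smallest qualifying threshold
    return float(candidates[best])


def choose_threshold(fit: SDMFit, rule: str | None = None) -> tuple[float, str]:
    """Pick the presence/absence threshold for one fitted species.

    With ``rule=None`` the rule is auto-selected by record count: 5-9
    records use 'sens_spec_equal', 10 or more use 'p10' (the 10th
    percentile, linear interpolation, of suitability at the training
    presences). Presence downstream means suitability >= threshold.
    Returns ``(threshold, rule_name)``.
    """
    if rule is None:
        rule = "sens_spec_equal" if fit.n_records <= 9 else "p10"
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {rule!r}")
    if rule == "p10":
        if fit.n_records < 10:
            logger.warning("p10 threshold for %s with only %d presences",
                           fit.species_id, fit.n_records)
        pres = np.asarray(sorted(fit.presences), dtype=int)
        return float(np.percentile(fit.suitability[pres], 10)), rule
    return _roc_threshold(fit, rule), rule


@dataclass
class PresenceAbsenceMatrix:
    """Binary cells x species matrix with per-species threshold metadata."""

    pa: pd.DataFrame  # int8, index cell_id, columns species
    thresholds: pd.DataFrame  # index species; columns threshold, rule, n_records

    @property
    def richness(self) -> pd.Series:
        """Per-cell species count (row sums)."""
        return self.pa.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.pa.shape[0]

    @property
    def species(self) -> list[str]:
        return list(self.pa.columns)

    def cell_sets(self) -> list[frozenset[str]]:
        """Species set per cell (for turnover computations)."""
        arr = self.pa.to_numpy()
        cols = np.asarray(self.pa.columns)
        return [frozenset(cols[np.flatnonzero(row)]) for row in arr]


def stack(fits: list[SDMFit], rule: str | None = None,
          ) -> PresenceAbsenceMatrix:
    """Threshold every species and assemble the presence/absence matrix.

    All fits must share the grid (equal suitability length). Species left
    with zero presence cells after thresholding are retained in the matrix
    but logged.
    """
    if not fits:
        raise ValueError("no fits to stack")
    n_cells = fits[0].suitability.size
    cols = {}
    meta = {}
    for fit in fits:
        if fit.suitability.size != n_cells:
            raise ValueError(f"grid mismatch for species {fit.species_id}")
        t, used_rule = choose_threshold(fit, rule)
        presence = (fit.suitability >= t).astype(np.int8)
        if presence.sum() == 0:
            logger.warning("species %s has zero presence cells after thresholding",
                           fit.species_id)
        cols[fit.species_id] = presence
        meta[fit.species_id] = {"threshold": t, "rule": used_rule,
                                "n_records": fit.n_records}
    pa = pd.DataFrame(cols, index=np.arange(n_cells))
    thresholds = pd.DataFrame.from_dict(meta, orient="index")
    return PresenceAbsenceMatrix(pa=pa, thresholds=thresholds)
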