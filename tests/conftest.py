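"""Shared synthetic worlds and helpers for the test suite.

Worlds are generated once per session; tests that mutate anything must
copy. Sizes are desk-scale: small enough for a laptop run, large enough to
exercise the sparse / intermediate / rich record-count regimes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sdmstack import make_world
from sdmstack.stacking import PresenceAbsenceMatrix


@pytest.fixture(scope="session")
def small_world():
    """Region-free world for SDM / drivers tests (720 cells, 6 predictors)."""
    return make_world(n_lon=30, n_lat=24, n_predictors=6, n_species=40,
                      seed=42)


@pytest.fixture(scope="session")
def region_world():
    """Four sharply separated regions with disjoint species pools."""
    return make_world(n_lon=24, n_lat=18, n_species=80, k_regions=4,
                      turnover_sharpness=5.0, seed=3)


@pytest.fixture(scope="session")
def region_pam(region_world):
    """Presence/absence truth of the region world (threshold 0.5)."""
    return PresenceAbsenceMatrix(pa=region_world.true_presence_absence(),
                                 thresholds=pd.DataFrame())


def random_pam(rng: np.random.Generator, n_cells: int = 30,
               n_species: int = 20, p: float = 0.3) -> PresenceAbsenceMatrix:
    """Random binary matrix wrapped as a stacked result."""
    M = (rng.random((n_cells, n_species)) < p).astype(np.int8)
    return PresenceAbsenceMatrix(
        pa=pd.DataFrame(M, columns=[f"sp{j}" for j in range(n_species)]),
        thresholds=pd.DataFrame())
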