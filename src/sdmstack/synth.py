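"""Synthetic virtual-species worlds with known truth.

Generates the ingredients the pipeline assumes in real data: smooth,
spatially autocorrelated environmental surfaces; virtual species with
Gaussian niches in predictor space; contiguous floristic regions with
controlled between-region species overlap; and road-corridor collection
bias. Every stage is deterministic under a fixed seed, so downstream
analyses (SDM recovery, bias tests, regionalization) can be checked against
the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .core import EnvMatrix, GridDomain, OccurrenceSet

__all__ = [
    "SyntheticWorld", "make_environment", "make_species", "make_regions",
    "make_bias_weights", "collect", "make_world",
]


@dataclass
class SyntheticWorld:
    """A complete virtual study system.

    ``true_suitability`` is n_species x n_cells in [0, 1]; ``true_regions``
    is a cluster label per cell (or None for a region-free world);
    ``bias_weights`` are per-cell sampling weights summing to 1.
    """

    grid: GridDomain
    env: EnvMatrix
    true_suitability: np.ndarray
    bias_weights: np.ndarray
    seed: int
    true_regions: np.ndarray | None = None
    species_names: list[str] = field(default_factory=list)
    pools: dict[int, list[int]] | None = None

    def __post_init__(self) -> None:
        s = self.true_suitability
        if s.min() < 0 or s.max() > 1:
            raise ValueError("true_suitability must lie in [0, 1]")
        if not np.isclose(self.bias_weights.sum(), 1.0):
            raise ValueError("bias_weights must sum to 1")
        if not self.species_names:
            self.species_names = [f"sp{i:04d}" for i in range(s.shape[0])]

    @property
    def n_species(self) -> int:
        return self.true_suitability.shape[0]

    def true_presence_absence(self, threshold: float = 0.5) -> pd.DataFrame:
        """Cells x species binary truth at a suitability cutoff."""
        pa = (self.true_suitability > threshold).T.astype(np.int8)
        return pd.DataFrame(pa, index=self.grid.cell_ids,
                            columns=self.species_names)


def _smooth_field(rng: np.random.Generator, n_lat: int, n_lon: int,
                  smoothness: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise field."""
    raw = rng.standard_normal((n_lat, n_lon))
    sm = gaussian_filter(raw, sigma=smoothness, mode="reflect")
    sd = sm.std()
    if sd == 0:
        return np.zeros_like(sm)
    return (sm - sm.mean()) / sd


def make_environment(n_lon: int, n_lat: int, n_predictors: int = 8,
                     smoothness: float = 5.0, seed: int = 0,
                     n_correlated: int = 0, target_rho: float = 0.9,
                     ) -> tuple[GridDomain, EnvMatrix]:
    """Generate a rectangular domain with smooth predictor surfaces.

    The first predictor ("temp_mean") carries a monotone latitudinal
    gradient, the second ("precip") a monotone longitudinal gradient; the
    remainder are pure smooth noise fields. ``n_correlated`` appends extra
    columns built to correlate with existing ones at about ``target_rho``
    (to exercise collinearity pruning); they count toward ``n_predictors``.
    """
    if n_lon < 4 or n_lat < 4:
        raise ValueError("grid must be at least 4 x 4")
    if n_predictors < 2:
        raise ValueError("need at least 2 predictors")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if n_correlated >= n_predictors - 1:
        raise ValueError("n_correlated must leave >= 2 base predictors")
    rng = np.random.default_rng(seed)
    grid = GridDomain.regular(n_lon, n_lat)
    lat_n = (grid.lat_center - grid.lat_center.mean()) / np.ptp(grid.lat_center)
    lon_n = (grid.lon_center - grid.lon_center.mean()) / np.ptp(grid.lon_center)

    def on_cells(field2d: np.ndarray) -> np.ndarray:
        return field2d.ravel()[grid._inside_flat]

    n_base = n_predictors - n_correlated
    cols: dict[str, np.ndarray] = {}
    # temperature-like: dominated by the latitudinal gradient (cooler north)
    cols["temp_mean"] = -3.0 * lat_n + 0.6 * on_cells(
        _smooth_field(rng, n_lat, n_lon, smoothness))
    # precipitation-like: longitudinal gradient (drier west)
    cols["precip"] = 3.0 * lon_n + 0.6 * on_cells(
        _smooth_field(rng, n_lat, n_lon, smoothness))
    for i in range(2, n_base):
        cols[f"env{i + 1:02d}"] = on_cells(
            _smooth_field(rng, n_lat, n_lon, smoothness))
    base_names = list(cols)
    for j in range(n_correlated):
        partner = base_names[j % len(base_names)]
        x = cols[partner]
        x = (x - x.mean()) / x.std()
        noise = on_cells(_smooth_field(rng, n_lat, n_lon, smoothness))
        rho = target_rho
        cols[f"{partner}_twin{j + 1}"] = rho * x + np.sqrt(1 - rho ** 2) * noise
    frame = pd.DataFrame(
        {k: (v - v.mean()) / v.std() for k, v in cols.items()},
        index=grid.cell_ids)
    return grid, EnvMatrix(frame)


def make_species(env: EnvMatrix, n_species: int = 200,
                 niche_breadth: float = 1.0,
                 prevalence_range: tuple[float, float] = (0.05, 0.25),
                 seed: int = 0, max_niche_dims: int = 3) -> np.ndarray:
    """Virtual species with Gaussian responses to 1-3 predictors.

    Each species responds to a random subset of predictors with a Gaussian
    niche centered on the predictor values of a random cell, so maximum
    suitability (1.0) is attained somewhere in the domain. The niche width
    is rescaled per species (bounded bisection) until the realized
    prevalence — the fraction of cells with suitability > 0.5 — falls
    inside ``prevalence_range``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    lo, hi = prevalence_range
    if not 0 < lo < hi < 1:
        raise ValueError("prevalence_range must satisfy 0 < lo < hi < 1")
    rng = np.random.default_rng(seed)
    z = env.values
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    n_cells, n_pred = z.shape
    out = np.empty((n_species, n_cells))
    for s in range(n_species):
        for attempt in range(12):
            ndim = int(rng.integers(1, min(max_niche_dims, n_pred) + 1))
            dims = rng.choice(n_pred, size=ndim, replace=False)
            center = z[rng.integers(n_cells), dims]
            d2 = ((z[:, dims] - center) ** 2).sum(axis=1)

            def prevalence(sigma: float) -> float:
                suit = np.exp(-d2 / (2 * sigma ** 2))
                return float((suit > 0.5).mean())

            target = rng.uniform(lo, hi)
            s_lo, s_hi = 1e-3 * niche_breadth, 1e3 * niche_breadth
            for _ in range(80):
                mid = np.sqrt(s_lo * s_hi)
                if prevalence(mid) < target:
                    s_lo = mid
                else:
                    s_hi = mid
            sigma = np.sqrt(s_lo * s_hi)
            if lo <= prevalence(sigma) <= hi:
                out[s] = np.exp(-d2 / (2 * sigma ** 2))
                break
        else:
            raise ValueError(
                f"could not reach prevalence_range {prevalence_range} for "
                f"species {s} after bounded rescaling attempts")
    return out


def make_bias_weights(grid: GridDomain, n_roads: int = 4,
                      corridor_sigma: float = 1.5, floor: float = 0.02,
                      seed: int = 0) -> np.ndarray:
    """Accessibility weights concentrated along random road corridors.

    A few random straight "roads" are rasterized onto the lattice and
    dilated into corridors by Gaussian smoothing; a small floor keeps every
    cell reachable. Weights are normalized to sum to 1 over inside cells.
    """
    rng = np.random.default_rng(seed)
    lattice = np.zeros((grid.n_lat, grid.n_lon))
    for _ in range(n_roads):
        a = rng.uniform([0, 0], [grid.n_lon - 1, grid.n_lat - 1])
        b = rng.uniform([0, 0], [grid.n_lon - 1, grid.n_lat - 1])
        t = np.linspace(0, 1, 4 * max(grid.n_lon, grid.n_lat))
        xs = np.round(a[0] + t * (b[0] - a[0])).astype(int)
        ys = np.round(a[1] + t * (b[1] - a[1])).astype(int)
        lattice[ys, xs] = 1.0
    corridors = gaussian_filter(lattice, sigma=corridor_sigma, mode="constant")
    if corridors.max() > 0:
        corridors /= corridors.max()
    w = corridors.ravel()[grid._inside_flat] + floor
    return w / w.sum()


def make_regions(grid: GridDomain, true_suitability: np.ndarray,
                 k_true: int, turnover_sharpness: float = 5.0,
                 pool_overlap: float = 0.0, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray, dict[int, list[int]]]:
    """Partition the domain into contiguous regions with distinct pools.

    Cells are split into ``k_true`` contiguous blocks (Voronoi cells of
    k-means on cell centers). A ``pool_overlap`` fraction of species stays
    cosmopolitan; the rest are dealt round-robin to regional pools and
    their suitability is damped outside the home region with a soft edge
    (e-folding distance ``1 / turnover_sharpness`` cells — large sharpness
    means hard region edges).

    Returns ``(true_regions, masked_suitability, pools)`` where ``pools``
    maps region label -> species indices endemic to it.
    """
    n_species, n_cells = true_suitability.shape
    if k_true < 2:
        raise ValueError("k_true must be >= 2")
    if k_true > n_cells:
        raise ValueError("k_true exceeds the number of cells")
    if turnover_sharpness <= 0:
        raise ValueError("turnover_sharpness must be positive")
    rng = np.random.default_rng(seed)
    xy = np.column_stack([grid.cell_cols.astype(float),
                          grid.cell_rows.astype(float)])
    _, labels = kmeans2(xy, k_true, minit="++", seed=rng.integers(2 ** 31))
    # k-means can drop a cluster on degenerate draws; relabel contiguously
    uniq = np.unique(labels)
    labels = np.searchsorted(uniq, labels)
    k_eff = uniq.size
    n_cosmo = int(round(pool_overlap * n_species))
    order = rng.permutation(n_species)
    cosmo = set(order[:n_cosmo].tolist())
    pools: dict[int, list[int]] = {r: [] for r in range(k_eff)}
    masked = true_suitability.copy()
    soft = 1.0 / turnover_sharpness
    # distance (in cell units) from every cell to each region's nearest cell
    dist_to_region = np.empty((k_eff, n_cells))
    for r in range(k_eff):
        dist_to_region[r] = cdist(xy, xy[labels == r]).min(axis=1)
    for rank, s in enumerate(order[n_cosmo:]):
        r = rank % k_eff
        pools[r].append(int(s))
        damp = np.exp(-(dist_to_region[r] / soft) ** 2)
        masked[s] = masked[s] * damp
    for r in pools:
        pools[r].sort()
    return labels, masked, pools


def collect(world: SyntheticWorld, effort: int = 5000,
            bias_strength: float = 1.0, seed: int = 0,
            ) -> tuple[OccurrenceSet, frozenset[int]]:
    """Simulate biased herbarium collecting.

    ``effort`` collection events each pick a cell with probability
    proportional to ``bias_weights ** bias_strength`` (0 gives spatially
    uniform collecting) and a uniformly random species; the event yields a
    record with Bernoulli(true suitability) probability — detection equals
    suitability, no false presences. Events are scaled so ``effort`` is
    the expected number of kept records. Returns the deduplicated
    occurrence set together with the distinct collection localities (cells
    holding at least one record), the unit the bias diagnostics and the
    null model operate on.
    """
    if effort <= 0:
        raise ValueError("effort must be positive")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    rng = np.random.default_rng(seed)
    n_cells = world.grid.n_cells
    if bias_strength == 0:
        w = np.full(n_cells, 1.0 / n_cells)
    else:
        w = world.bias_weights ** bias_strength
        w = w / w.sum()
    # scale visit events so the EXPECTED number of kept records equals effort
    mean_accept = float(world.true_suitability.mean(axis=0) @ w)
    n_events = int(np.ceil(effort / max(mean_accept, 1e-12)))
    cells = rng.choice(n_cells, size=n_events, p=w)
    species = rng.integers(world.n_species, size=n_events)
    keep = rng.random(n_events) < world.true_suitability[species, cells]
    presences: dict[str, set[int]] = {}
    for s, c in zip(species[keep], cells[keep]):
        presences.setdefault(world.species_names[s], set()).add(int(c))
    # collection localities = cells holding at least one record, the unit
    # the bias diagnostics and null model operate on
    localities = frozenset(int(c) for c in np.unique(cells[keep]))
    return OccurrenceSet(presences), localities


def make_world(n_lon: int = 40, n_lat: int = 30, n_predictors: int = 8,
               n_species: int = 200, smoothness: float = 5.0,
               niche_breadth: float = 1.0,
               prevalence_range: tuple[float, float] = (0.05, 0.25),
               k_regions: int | None = None,
               turnover_sharpness: float = 5.0, pool_overlap: float = 0.0,
               n_correlated: int = 0, seed: int = 0) -> SyntheticWorld:
    """Assemble a full synthetic world (environment, species, bias, regions).

    Defaults give the desk-scale study system: a 40 x 30 grid (1,200
    cells), 8 predictors, 200 species whose record counts span the sparse
    (5-10), intermediate (11-14) and rich (>= 15) regimes under the default
    collecting effort of 5,000 events.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    grid, env = make_environment(n_lon, n_lat, n_predictors, smoothness,
                                 seed=ss[0], n_correlated=n_correlated)
    suit = make_species(env, n_species, niche_breadth, prevalence_range,
                        seed=ss[1])
    regions = None
    pools = None
    if k_regions is not None:
        regions, suit, pools = make_regions(
            grid, suit, k_regions, turnover_sharpness, pool_overlap,
            seed=ss[2])
    bias = make_bias_weights(grid, seed=ss[3])
    return SyntheticWorld(grid=grid, env=env, true_suitability=suit,
                          bias_weights=bias, seed=seed, true_regions=regions,
                          pools=pools)
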