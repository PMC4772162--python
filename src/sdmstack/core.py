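"""Grid-indexed data model shared by every pipeline stage.

The study domain is a regular longitude/latitude lattice of square cells
(edge length given in arc-minutes) with an inside/outside mask. All
downstream containers — environmental matrices, occurrence sets,
presence/absence matrices — are indexed by the contiguous cell ids
``0..n_cells-1`` enumerating the inside cells in row-major (south-to-north,
west-to-east) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GridDomain", "EnvMatrix", "OccurrenceSet"]


@dataclass(frozen=True)
class GridDomain:
    """A bounded lon/lat cell lattice.

    Cells are half-open intervals ``[lon0 + i*step, lon0 + (i+1)*step) x
    [lat0 + j*step, lat0 + (j+1)*step)`` with the origin at the domain's
    lower-left (south-west) corner, so every coordinate maps to exactly one
    cell. ``resolution`` is the cell edge in arc-minutes (10 for a
    10-arc-minute grid); ``step = resolution / 60`` degrees.

    ``mask`` has shape ``(n_lat, n_lon)``; row 0 is the southernmost row.
    Only masked-in cells receive cell ids and participate in analyses.
    """

    n_lon: int
    n_lat: int
    lon0: float
    lat0: float
    resolution: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive arc-minutes")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.n_lat, self.n_lon):
            raise ValueError(
                f"mask shape {mask.shape} != (n_lat={self.n_lat}, n_lon={self.n_lon})"
            )
        object.__setattr__(self, "mask", mask)
        # lattice index (row-major over the full rectangle) -> cell id, -1 outside
        lattice_to_cell = np.full(self.n_lat * self.n_lon, -1, dtype=np.int64)
        inside = np.flatnonzero(mask.ravel())
        lattice_to_cell[inside] = np.arange(inside.size)
        object.__setattr__(self, "_lattice_to_cell", lattice_to_cell)
        object.__setattr__(self, "_inside_flat", inside)

    @property
    def step(self) -> float:
        """Cell edge in decimal degrees."""
        return self.resolution / 60.0

    @property
    def n_cells(self) -> int:
        return int(self._inside_flat.size)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    @property
    def cell_rows(self) -> np.ndarray:
        """Latitude row index (0 = southernmost) of each inside cell."""
        return self._inside_flat // self.n_lon

    @property
    def cell_cols(self) -> np.ndarray:
        """Longitude column index (0 = westernmost) of each inside cell."""
        return self._inside_flat % self.n_lon

    @property
    def lon_center(self) -> np.ndarray:
        return self.lon0 + (self.cell_cols + 0.5) * self.step

    @property
    def lat_center(self) -> np.ndarray:
        return self.lat0 + (self.cell_rows + 0.5) * self.step

    def point_to_cell(self, lon, lat) -> np.ndarray:
        """Map coordinates to cell ids (-1 for points outside the domain).

        Half-open intervals: a point on a shared edge belongs to the cell
        whose lower/left edge it sits on.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - self.lon0) / self.step).astype(np.int64)
        iy = np.floor((lat - self.lat0) / self.step).astype(np.int64)
        ok = (ix >= 0) & (ix < self.n_lon) & (iy >= 0) & (iy < self.n_lat)
        out = np.full(np.broadcast(ix, iy).shape, -1, dtype=np.int64)
        flat = iy[ok] * self.n_lon + ix[ok]
        out[ok] = self._lattice_to_cell[flat]
        return out

    def to_lattice(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-cell values onto the full (n_lat, n_lon) lattice."""
        values = np.asarray(values)
        if values.shape[0] != self.n_cells:
            raise ValueError("values must have one entry per inside cell")
        grid = np.full((self.n_lat * self.n_lon,), fill, dtype=float)
        grid[self._inside_flat] = values
        return grid.reshape(self.n_lat, self.n_lon)

    def submask(self, keep: np.ndarray) -> "GridDomain":
        """New domain keeping only the inside cells flagged in ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_cells,):
            raise ValueError("keep must be a boolean per inside cell")
        new_mask = np.zeros(self.n_lat * self.n_lon, dtype=bool)
        new_mask[self._inside_flat[keep]] = True
        return GridDomain(
            self.n_lon, self.n_lat, self.lon0, self.lat0, self.resolution,
            new_mask.reshape(self.n_lat, self.n_lon),
        )

    @staticmethod
    def regular(n_lon: int, n_lat: int, lon0: float = 100.0, lat0: float = 30.0,
                resolution: float = 10.0) -> "GridDomain":
        """Fully-inside rectangular domain (convenience constructor)."""
        return GridDomain(n_lon, n_lat, lon0, lat0, resolution,
                          np.ones((n_lat, n_lon), dtype=bool))


class EnvMatrix:
    """Cells x named-predictors matrix.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by cell id with
    stable, name-addressable columns; no missing values are allowed inside
    the domain (resolved at load time).
    """

    def __init__(self, data: pd.DataFrame, units: Mapping[str, str] | None = None):
        if data.columns.duplicated().any():
            raise ValueError("duplicate predictor names")
        if data.isna().any().any():
            raise ValueError("EnvMatrix must not contain missing values")
        self.data = data.astype(float)
        self.units = dict(units or {})

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def subset(self, names: Iterable[str]) -> "EnvMatrix":
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown predictors: {missing}")
        return EnvMatrix(self.data[names],
                         {k: v for k, v in self.units.items() if k in names})

    def rows(self, cell_ids: np.ndarray) -> "EnvMatrix":
        return EnvMatrix(self.data.iloc[np.asarray(cell_ids)], self.units)

    def __eq__(self, other) -> bool:
        return isinstance(other, EnvMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"EnvMatrix({self.n_cells} cells x {len(self.names)} predictors)"


class OccurrenceSet:
    """Deduplicated species -> presence-cell sets.

    One "record" is one distinct (species, cell) pair; repeated collections
    of a species inside one cell collapse to a single presence.
    """

    def __init__(self, presences: Mapping[str, Iterable[int]]):
        self._sets: dict[str, frozenset[int]] = {
            str(sp): frozenset(int(c) for c in cells)
            for sp, cells in presences.items()
        }

    @property
    def species(self) -> list[str]:
        return sorted(self._sets)

    def cells(self, species: str) -> frozenset[int]:
        return self._sets[species]

    def n_records(self, species: str) -> int:
        return len(self._sets[species])

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, species: str) -> bool:
        return species in self._sets

    def __iter__(self):
        return iter(self.species)

    def all_cells(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self._sets.values():
            out |= s
        return frozenset(out)

    def filter_min_cells(self, min_cells: int) -> tuple["OccurrenceSet", list[str]]:
        """Drop species present in fewer than ``min_cells`` distinct cells."""
        kept = {s: c for s, c in self._sets.items() if len(c) >= min_cells}
        dropped = sorted(set(self._sets) - set(kept))
        return OccurrenceSet(kept), dropped

    def to_frame(self) -> pd.DataFrame:
        """Long-format (species, cell_id) table, sorted for stable dumps."""
        rows = [(sp, c) for sp in self.species for c in sorted(self._sets[sp])]
        return pd.DataFrame(rows, columns=["species", "cell_id"])

    def __eq__(self, other) -> bool:
        return isinstance(other, OccurrenceSet) and self._sets == other._sets
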