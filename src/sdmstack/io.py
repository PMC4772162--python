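"""Readers and writers for occurrences, rasters and matrices.

Supported formats are plain text throughout: delimited occurrence tables
(``species,lon,lat``), ESRI ASCII grids for rasters, dense CSV and sparse
coordinate-triplet text for matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EnvMatrix, GridDomain, OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "load_occurrences", "dump_occurrences", "OccurrenceLoadReport",
    "read_ascii_grid", "write_ascii_grid", "raster_to_column",
    "load_env_rasters", "write_matrix", "read_matrix",
]


@dataclass
class OccurrenceLoadReport:
    """Bookkeeping from :func:`load_occurrences`."""

    n_rows: int
    n_bad_rows: int
    n_outside: int
    dropped_species: list[str]


def load_occurrences(path, grid: GridDomain, min_cells: int = 5,
                     ) -> tuple[OccurrenceSet, OccurrenceLoadReport]:
    """Load a ``species,lon,lat`` delimited file onto the grid.

    Coordinates are snapped to cells, per-species cell sets are
    deduplicated, and species occupying fewer than ``min_cells`` distinct
    cells are dropped (default 5). Unparseable rows and coordinates outside
    the domain are skipped and counted in the report.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence file must have columns {sorted(required)}")
    n_rows = len(df)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | df["species"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("skipped %d unparseable occurrence rows", n_bad)
    df = df.loc[~bad]
    cell = grid.point_to_cell(lon[~bad].to_numpy(), lat[~bad].to_numpy())
    outside = cell < 0
    n_outside = int(outside.sum())
    if n_outside:
        logger.warning("skipped %d occurrences outside the domain", n_outside)
    sp = df["species"].astype(str).to_numpy()[~outside]
    cell = cell[~outside]
    presences: dict[str, set[int]] = {}
    for s, c in zip(sp, cell):
        presences.setdefault(s, set()).add(int(c))
    occ = OccurrenceSet(presences)
    occ, dropped = occ.filter_min_cells(min_cells)
    if len(occ) == 0:
        raise ValueError("no species retained after filtering; check inputs")
    return occ, OccurrenceLoadReport(n_rows, n_bad, n_outside, dropped)


def dump_occurrences(occ: OccurrenceSet, grid: GridDomain, path) -> None:
    """Write occurrences back as cell-center coordinates (round-trippable)."""
    frame = occ.to_frame()
    frame["lon"] = grid.lon_center[frame["cell_id"]]
    frame["lat"] = grid.lat_center[frame["cell_id"]]
    frame[["species", "lon", "lat"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns ``(values, header)`` where ``values`` has shape (nrows, ncols)
    with row 0 the SOUTHERNMOST row (flipped from file order, which is
    north-first), and header keys ``ncols, nrows, xllcorner, yllcorner,
    cellsize, nodata_value``. NODATA cells become NaN.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = []
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                lines.append(line)
                break
        body = "".join(lines) + fh.read()
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing header)")
    values = np.array(body.split(), dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.size != ncols * nrows:
        raise ValueError(f"{path}: expected {ncols * nrows} values, got {values.size}")
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values[::-1], header


def write_ascii_grid(path, values: np.ndarray, xllcorner: float,
                     yllcorner: float, cellsize: float,
                     nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; ``values`` row 0 is the southernmost row."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.isnan(values), nodata_value, values)[::-1]
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\n")
        fh.write(f"yllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def raster_to_column(values: np.ndarray, header: dict, grid: GridDomain,
                     categorical: bool = False) -> np.ndarray:
    """Resample one raster onto the analysis grid.

    Continuous layers aggregate by the mean of raster cells whose centers
    fall inside each grid cell; categorical layers take the raster value at
    the grid-cell center (nearest neighbour, no averaging). Grid cells not
    covered by any raster cell come back NaN.
    """
    nrows, ncols = values.shape
    x0, y0, cs = header["xllcorner"], header["yllcorner"], header["cellsize"]
    if categorical:
        cx, cy = grid.lon_center, grid.lat_center
        ix = np.floor((cx - x0) / cs).astype(int)
        iy = np.floor((cy - y0) / cs).astype(int)
        ok = (ix >= 0) & (ix < ncols) & (iy >= 0) & (iy < nrows)
        out = np.full(grid.n_cells, np.nan)
        out[ok] = values[iy[ok], ix[ok]]
        return out
    # continuous: group raster-cell centers by target grid cell, average
    xs = x0 + (np.arange(ncols) + 0.5) * cs
    ys = y0 + (np.arange(nrows) + 0.5) * cs
    xx, yy = np.meshgrid(xs, ys)
    cell = grid.point_to_cell(xx.ravel(), yy.ravel())
    val = values.ravel()
    ok = (cell >= 0) & ~np.isnan(val)
    sums = np.bincount(cell[ok], weights=val[ok], minlength=grid.n_cells)
    counts = np.bincount(cell[ok], minlength=grid.n_cells)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def load_env_rasters(paths, grid: GridDomain, categorical=(),
                     names=None) -> tuple[EnvMatrix, GridDomain]:
    """Load ESRI ASCII rasters and resample each onto the grid.

    ``categorical`` names layers resampled by nearest neighbour instead of
    mean aggregation. Cells with a missing value in any layer are excluded
    from the returned (possibly shrunken) domain, with a logged count.
    Returns ``(env, grid)`` where ``grid`` is the (possibly reduced) domain.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    cols = {}
    for name, p in zip(names, paths):
        values, header = read_ascii_grid(p)
        col = raster_to_column(values, header, grid, categorical=name in set(categorical))
        if np.isnan(col).all():
            raise ValueError(f"raster layer {name!r} has no data over the domain")
        if np.isnan(col).sum() == grid.n_cells:
            raise ValueError(f"raster {name!r} does not cover the domain")
        cols[name] = col
    frame = pd.DataFrame(cols, index=grid.cell_ids)
    missing = frame.isna().any(axis=1).to_numpy()
    if missing.all():
        raise ValueError("no grid cell is covered by all raster layers")
    if missing.any():
        logger.warning("excluding %d cells with missing environmental values",
                       int(missing.sum()))
        grid = grid.submask(~missing)
        frame = frame.loc[~missing].reset_index(drop=True)
        frame.index = grid.cell_ids
    return EnvMatrix(frame), grid


# ---------------------------------------------------------------------------
# Matrix round-trips


def write_matrix(matrix: pd.DataFrame, path, sparse: bool = False) -> None:
    """Write a named-row/column matrix as dense CSV or sparse triplet text.

    The sparse codec writes ``row_label<TAB>col_label<TAB>value`` for each
    non-zero entry, after a first line ``#shape nrows ncols`` and label
    lines, so an all-zero matrix round-trips as a header-only file.
    """
    path = Path(path)
    if not sparse:
        matrix.to_csv(path)
        return
    with open(path, "w") as fh:
        fh.write(f"#shape\t{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("#rows\t" + "\t".join(map(str, matrix.index)) + "\n")
        fh.write("#cols\t" + "\t".join(map(str, matrix.columns)) + "\n")
        arr = matrix.to_numpy()
        for i, j in zip(*np.nonzero(arr)):
            fh.write(f"{matrix.index[i]}\t{matrix.columns[j]}\t{arr[i, j]:.10g}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (either codec)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#shape"):
        return pd.read_csv(path, index_col=0)
    with open(path) as fh:
        _, nr, nc = fh.readline().split("\t")
        rows = fh.readline().rstrip("\n").split("\t")[1:]
        cols = fh.readline().rstrip("\n").split("\t")[1:]
        arr = np.zeros((int(nr), int(nc)))
        ridx = {r: i for i, r in enumerate(rows)}
        cidx = {c: j for j, c in enumerate(cols)}
        for line in fh:
            r, c, v = line.rstrip("\n").split("\t")
            arr[ridx[r], cidx[c]] = float(v)
    frame = pd.DataFrame(arr, index=rows, columns=cols)
    # restore integer labels where possible (cell ids)
    try:
        frame.index = frame.index.astype(int)
    except (TypeError, ValueError):
        pass
    return frame
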