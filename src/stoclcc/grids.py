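"""Categorical land-cover grids, dated series, driver feature layers, and raster I/O.

The data model is a rectangular grid of three land-cover states —
deforested (0), forest (1) and regeneration (2) — plus a nodata code for
water and missing cells.  A series of dated grids shares one shape, one
cell size and one common nodata mask (the union of the per-date masks,
mirroring a water mask applied to every date of a satellite time series).

Supported on-disk formats are the ESRI ASCII grid (plain text, carries
cell size and nodata value in its header) and single-band integer TIFF.
Row 0 is north; indices are (row, col), 0-based; cell centres define
positions for distance computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

#: Land-cover state codes.  The change-coding of map pairs relies on these
#: exact integers (deforested=0, forest=1, regeneration=2).
DEFORESTED = 0
FOREST = 1
REGEN = 2
NODATA = -1

STATE_NAMES = {DEFORESTED: "deforested", FOREST: "forest", REGEN: "regeneration"}
_VALID_CODES = frozenset((DEFORESTED, FOREST, REGEN, NODATA))

#: Default class map: raster values already use the internal coding.
IDENTITY_CLASS_MAP = {0: DEFORESTED, 1: FOREST, 2: REGEN, -1: NODATA}

_ASCII_NODATA = -9999


class GridError(ValueError):
    """Raised for malformed rasters, inconsistent series or bad class maps."""


@dataclass
class LandCoverGrid:
    """One dated categorical land-cover map.

    Parameters
    ----------
    year : int
        Calendar year of the observation.
    cells : ndarray of int8, shape (nrows, ncols)
        State codes; any value outside {0, 1, 2, NODATA} is rejected.
    cell_size : float
        Cell edge length in metres (default 30, Landsat scale).
    """

    year: int
    cells: np.ndarray
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2 or cells.size == 0:
            raise GridError("land-cover grid must be a non-empty 2-D array")
        bad = set(np.unique(cells)) - _VALID_CODES
        if bad:
            raise GridError(f"invalid state codes in grid: {sorted(bad)}")
        self.cells = cells.astype(np.int8, copy=False)
        self.year = int(self.year)
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell is NODATA."""
        return self.cells == NODATA

    @property
    def valid_mask(self) -> np.ndarray:
        return self.cells != NODATA

    def copy(self) -> "LandCoverGrid":
        return LandCoverGrid(self.year, self.cells.copy(), self.cell_size)

    def with_cells(self, cells: np.ndarray, year: int | None = None) -> "LandCoverGrid":
        return LandCoverGrid(self.year if year is None else year, cells, self.cell_size)


@dataclass
class LandCoverSeries:
    """Ordered, dated stack of land-cover grids sharing shape, cell size and mask."""

    grids: list[LandCoverGrid]

    def __post_init__(self) -> None:
        if len(self.grids) < 2:
            raise GridError("a series needs at least two dated grids")
        years = [g.year for g in self.grids]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise GridError("series years must be strictly increasing")
        shapes = {g.shape for g in self.grids}
        if len(shapes) != 1:
            raise GridError(f"series grids differ in shape: {sorted(shapes)}")
        sizes = {g.cell_size for g in self.grids}
        if len(sizes) != 1:
            raise GridError("series grids differ in cell size")
        mask0 = self.grids[0].nodata_mask
        for g in self.grids[1:]:
            if not np.array_equal(g.nodata_mask, mask0):
                raise GridError(
                    "series grids disagree on the nodata mask; build with build_series()"
                )

    @property
    def years(self) -> list[int]:
        return [g.year for g in self.grids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def cell_size(self) -> float:
        return self.grids[0].cell_size

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.grids[0].nodata_mask

    def grid_for(self, year: int) -> LandCoverGrid:
        for g in self.grids:
            if g.year == year:
                return g
        raise KeyError(f"year {year} not in series years {self.years}")

    def upto(self, year: int) -> "LandCoverSeries":
        """Sub-series of all grids dated <= year (at least two required)."""
        grids = [g for g in self.grids if g.year <= year]
        return LandCoverSeries(grids)


@dataclass
class FeatureLayers:
    """Static driver features as boolean masks sharing the series shape.

    ``roads``, ``rivers`` and ``settlements`` mark feature cells (distance
    sources); ``protected`` marks cells inside a protected area.
    """

    roads: np.ndarray
    rivers: np.ndarray
    settlements: np.ndarray
    protected: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        shape = None
        for name in ("roads", "rivers", "settlements", "protected"):
            a = np.asarray(getattr(self, name), dtype=bool)
            if a.ndim != 2:
                raise GridError(f"feature layer {name!r} must be 2-D")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise GridError("feature layers differ in shape")
            arrays[name] = a
        for name, a in arrays.items():
            setattr(self, name, a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.roads.shape


def build_series(grids: Sequence[LandCoverGrid]) -> LandCoverSeries:
    """Assemble dated grids into a series under the common-mask convention.

    Grids are sorted by year and the union of per-date nodata masks is
    applied to every date, so a cell missing in any one map is excluded
    from the whole analysis.
    """
    if len(grids) < 2:
        raise GridError("need at least two grids to build a series")
    years = [g.year for g in grids]
    if len(set(years)) != len(years):
        raise GridError(f"duplicate years in series: {sorted(years)}")
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise GridError(f"grids differ in shape: {sorted(shapes)}")
    ordered = sorted(grids, key=lambda g: g.year)
    common = np.zeros(ordered[0].shape, dtype=bool)
    for g in ordered:
        common |= g.nodata_mask
    masked = []
    for g in ordered:
        cells = g.cells.copy()
        cells[common] = NODATA
        masked.append(LandCoverGrid(g.year, cells, g.cell_size))
    return LandCoverSeries(masked)


# ---------------------------------------------------------------------------
# Raster I/O


def _apply_class_map(values: np.ndarray, class_map: Mapping[int, int]) -> np.ndarray:
    out = np.full(values.shape, NODATA, dtype=np.int8)
    seen = np.zeros(values.shape, dtype=bool)
    for raw, state in class_map.items():
        if state not in _VALID_CODES:
            raise GridError(f"class_map maps {raw} to invalid state {state}")
        hit = values == raw
        out[hit] = state
        seen |= hit
    if not seen.all():
        unmapped = sorted(set(np.unique(values[~seen])))
        raise GridError(f"raster values with no class_map entry: {unmapped}")
    return out


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, float]:
    """Parse an ESRI ASCII grid; returns (values, cellsize, nodata_value)."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            m = re.match(r"^([A-Za-z_]+)\s+(\S+)$", stripped)
            if m and not data_lines and m.group(1).lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[m.group(1).lower()] = float(m.group(2))
            else:
                data_lines.append(stripped)
    for key in ("ncols", "nrows"):
        if key not in header:
            raise GridError(f"ESRI ASCII grid {path} missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        values = np.array(" ".join(data_lines).split(), dtype=np.float64)
    except ValueError as exc:
        raise GridError(f"cannot parse grid body of {path}: {exc}") from exc
    if values.size != nrows * ncols:
        raise GridError(
            f"{path}: expected {nrows * ncols} values, found {values.size} (nonrectangular?)"
        )
    values = values.reshape(nrows, ncols)
    return values, header.get("cellsize", 30.0), header.get("nodata_value", _ASCII_NODATA)


def read_landcover(
    path: str | Path,
    year: int,
    class_map: Mapping[int, int] | None = None,
    cell_size: float | None = None,
) -> LandCoverGrid:
    """Read a single-band raster as a dated land-cover grid.

    ``class_map`` maps raster values onto the internal state codes; the
    ASCII header's nodata value is mapped to NODATA automatically.  Values
    without a mapping raise :class:`GridError`.
    """
    path = Path(path)
    class_map = dict(IDENTITY_CLASS_MAP if class_map is None else class_map)
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        values, cs, nodata_value = _read_ascii_grid(path)
        class_map.setdefault(int(nodata_value), NODATA)
        cells = _apply_class_map(values.astype(np.int64), class_map)
        return LandCoverGrid(year, cells, cell_size if cell_size is not None else cs)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values = np.asarray(tifffile.imread(path))
        if values.ndim != 2:
            raise GridError(f"{path}: expected a single-band raster")
        cells = _apply_class_map(values.astype(np.int64), class_map)
        return LandCoverGrid(year, cells, cell_size if cell_size is not None else 30.0)
    raise GridError(f"unsupported raster format: {path.suffix!r}")


def write_landcover(grid: LandCoverGrid, path: str | Path) -> Path:
    """Write a grid as ESRI ASCII (.asc) or single-band TIFF (.tif)."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        write_ascii_grid(grid.cells, path, cell_size=grid.cell_size,
                         nodata_from=NODATA, nodata_value=_ASCII_NODATA)
        return path
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, grid.cells.astype(np.int16))
        return path
    raise GridError(f"unsupported raster format: {path.suffix!r}")


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    cell_size: float = 30.0,
    nodata_from: int | float | None = None,
    nodata_value: float = _ASCII_NODATA,
    fmt: str = "%d",
) -> Path:
    """Write any 2-D array as an ESRI ASCII grid."""
    values = np.asarray(values)
    out = values.astype(np.float64).copy()
    if nodata_from is not None:
        out[values == nodata_from] = nodata_value
    nrows, ncols = out.shape
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size:g}\n")
        fh.write(f"NODATA_value {nodata_value:g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")
    return path
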