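"""Predictor grids for the transition models.

Two kinds of covariate feed the per-pixel logistic models:

* **static** layers computed once per landscape — Euclidean distance to
  roads, rivers and settlements (metres) and a protected-area indicator;
* **dynamic** layers recomputed from the current map at every simulation
  step — the contagion proportions (fraction of neighbours already
  deforested / in regeneration) and three land-use history metrics
  derived from the map time series:

  - ``palu``: period of active land use — calendar years the cell spent
    deforested before its most recent abandonment (regeneration onset);
  - ``arf``: age of regenerating forest — years since that abandonment,
    for cells currently in regeneration;
  - ``fc``: frequency of clearance — number of observed transitions into
    the deforested state up to the query year.

States between observation dates are treated as piecewise-constant
(last observation carried forward); a transition is attributed to the
later date of the bracketing pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grids import (
    DEFORESTED,
    FOREST,
    NODATA,
    REGEN,
    FeatureLayers,
    GridError,
    LandCoverGrid,
    LandCoverSeries,
)

#: Canonical layer names, in reporting order.
LAYER_NAMES = (
    "dist_roads",
    "dist_rivers",
    "dist_settlements",
    "protected",
    "contagion_defor",
    "contagion_regen",
    "palu",
    "arf",
    "fc",
)
STATIC_LAYERS = ("dist_roads", "dist_rivers", "dist_settlements", "protected")
DYNAMIC_LAYERS = ("contagion_defor", "contagion_regen", "palu", "arf", "fc")
#: History metrics are only meaningful for cells with a clearance history,
#: and are offered only to the regeneration->deforested candidate set.
HISTORY_LAYERS = ("palu", "arf", "fc")


@dataclass
class CovariateStack:
    """All predictor layers for one date, sharing the series shape and mask."""

    year: int
    layers: dict[str, np.ndarray]
    valid_mask: np.ndarray
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        shape = self.valid_mask.shape
        for name, layer in self.layers.items():
            if layer.shape != shape:
                raise GridError(f"layer {name!r} shape {layer.shape} != {shape}")

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"no covariate layer {name!r}; have {sorted(self.layers)}"
            ) from None

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid_mask.shape


def distance_grid(mask: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """Euclidean distance (metres) from each cell centre to the nearest feature cell.

    Zero on feature cells themselves.  Raises on an empty mask (a distance
    to nothing is undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GridError("distance_grid: feature mask is empty")
    return ndimage.distance_transform_edt(~mask, sampling=cell_size)


def contagion(
    grid: LandCoverGrid | np.ndarray, target_state: int, radius: int = 1
) -> np.ndarray:
    """Proportion of valid neighbours in ``target_state``.

    The neighbourhood is the square (Moore) window of half-width ``radius``
    with the centre cell excluded; the count is normalised by the number of
    valid (in-bounds, non-NODATA) neighbours, so edge and coast cells use
    their actual neighbour count.  NODATA cells get 0.
    """
    if radius < 1:
        raise ValueError("contagion radius must be >= 1")
    cells = grid.cells if isinstance(grid, LandCoverGrid) else np.asarray(grid)
    valid = (cells != NODATA).astype(np.float64)
    target = ((cells == target_state) & (cells != NODATA)).astype(np.float64)
    k = 2 * radius + 1
    kernel = np.ones((k, k))
    hits = ndimage.correlate(target, kernel, mode="constant", cval=0.0) - target
    n_valid = ndimage.correlate(valid, kernel, mode="constant", cval=0.0) - valid
    out = np.zeros_like(hits)
    np.divide(hits, n_valid, out=out, where=n_valid > 0)
    # correlate sums can carry tiny float error; clip to the unit interval
    np.clip(out, 0.0, 1.0, out=out)
    out[cells == NODATA] = 0.0
    return out


def _history_from_grids(
    cell_stacks: Sequence[np.ndarray], years: Sequence[int], upto_year: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised trace of per-cell clearance history up to ``upto_year``."""
    years = list(years)
    if upto_year not in years:
        raise GridError(f"year {upto_year} not among observation years {years}")
    stop = years.index(upto_year)
    shape = cell_stacks[0].shape

    fc = np.zeros(shape, dtype=np.int32)
    clear_start = np.full(shape, -1, dtype=np.int32)   # year current D interval began
    regen_year = np.full(shape, -1, dtype=np.int32)    # year of most recent D->R onset
    palu_at_regen = np.zeros(shape, dtype=np.int32)

    first = cell_stacks[0]
    clear_start[first == DEFORESTED] = years[0]
    prev = first
    for i in range(1, stop + 1):
        cur = cell_stacks[i]
        year = years[i]
        became_d = (cur == DEFORESTED) & (prev != DEFORESTED) & (prev != NODATA)
        fc[became_d & ((prev == FOREST) | (prev == REGEN))] += 1
        clear_start[became_d] = year
        became_r = (cur == REGEN) & (prev == DEFORESTED)
        regen_year[became_r] = year
        palu_at_regen[became_r] = year - clear_start[became_r]
        # regeneration arising otherwise (e.g. classified straight from forest)
        became_r_other = (cur == REGEN) & (prev != DEFORESTED) & (prev != REGEN) & (prev != NODATA)
        regen_year[became_r_other] = year
        palu_at_regen[became_r_other] = 0
        prev = cur

    final = cell_stacks[stop]
    currently_regen = (final == REGEN) & (regen_year >= 0)
    arf = np.where(currently_regen, upto_year - regen_year, 0).astype(np.float64)
    palu = np.where(currently_regen, palu_at_regen, 0).astype(np.float64)
    return palu, arf, fc.astype(np.float64)


def history_metrics(
    series: LandCoverSeries, upto_year: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PALU, ARF and FC grids from the observed series up to ``upto_year``.

    Example: a cell observed forest (1990), deforested (1995), regeneration
    (2000) and queried at 2011 has fc=1, arf=11 and palu=5 under the
    carried-forward convention.
    """
    return _history_from_grids([g.cells for g in series.grids], series.years, upto_year)


def compute_static_layers(
    features: FeatureLayers, cell_size: float = 30.0
) -> dict[str, np.ndarray]:
    """Distance and protection layers; cache and reuse across dates."""
    return {
        "dist_roads": distance_grid(features.roads, cell_size),
        "dist_rivers": distance_grid(features.rivers, cell_size),
        "dist_settlements": distance_grid(features.settlements, cell_size),
        "protected": features.protected.astype(np.float64),
    }


def assemble_stack(
    current: LandCoverGrid,
    series: LandCoverSeries,
    features: FeatureLayers,
    year: int | None = None,
    radius: int = 1,
    static: Mapping[str, np.ndarray] | None = None,
) -> CovariateStack:
    """Build the full nine-layer covariate stack for one date.

    ``current`` is the map providing the dynamic contagion layers (during
    simulation this is the simulated map); ``series`` supplies the history
    for PALU/ARF/FC and must contain the stack year.  Static layers are
    recomputed unless a cached mapping from :func:`compute_static_layers`
    is passed in.
    """
    if features.shape != current.shape:
        raise GridError(
            f"feature shape {features.shape} != map shape {current.shape}"
        )
    year = current.year if year is None else int(year)
    layers = dict(static) if static is not None else compute_static_layers(
        features, current.cell_size
    )
    layers["contagion_defor"] = contagion(current, DEFORESTED, radius)
    layers["contagion_regen"] = contagion(current, REGEN, radius)
    palu, arf, fc = history_metrics(series, year)
    layers.update(palu=palu, arf=arf, fc=fc)
    return CovariateStack(
        year=year,
        layers=layers,
        valid_mask=current.valid_mask,
        cell_size=current.cell_size,
    )


def write_stack(stack: CovariateStack, path: str | Path) -> Path:
    """Dump all layers as a multi-band float TIFF (band order = LAYER_NAMES)."""
    import tifffile

    bands = np.stack([stack.layer(n).astype(np.float32) for n in LAYER_NAMES])
    tifffile.imwrite(Path(path), bands, metadata={"axes": "CYX"})
    return Path(path)
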