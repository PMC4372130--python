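"""Change-coding of map pairs and the perfect-match validation metric.

A pair of maps (initial, final) is reduced to a change-code grid over the
three modelled transitions: 1 where forest became deforested, 2 where
regeneration became deforested, 3 where deforested became regeneration,
0 everywhere else (no change, or an unmodelled transition).

Perfect match compares the observed change-code grid with each predicted
one (one per stochastic iteration): the percentage of observed changed
cells whose exact transition code is reproduced at the exact location,
i.e. 100 * |{x : obs(x) = pred(x), obs(x) != 0}| / |{x : obs(x) != 0}|.
Only observed change enters the denominator, so cells that do not change
over the period are never validated — and predicted change at locations
with no observed change is not penalised by this metric (a documented
property of the definition, not an implementation shortcut).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import DEFORESTED, FOREST, NODATA, REGEN, GridError, LandCoverGrid

NO_MODELLED_CHANGE = 0
CODE_FTOD = 1
CODE_RTOD = 2
CODE_DTOR = 3
CODE_NODATA = -1


@dataclass
class ChangeCodeGrid:
    """Grid of transition codes between two dated maps."""

    codes: np.ndarray
    initial_year: int
    final_year: int

    @property
    def n_changes(self) -> int:
        return int(np.count_nonzero((self.codes > 0)))


@dataclass
class PerfectMatchResult:
    """Perfect-match percentages across stochastic iterations."""

    per_iteration: np.ndarray
    mean: float
    n_observed_changes: int


def change_code(initial: LandCoverGrid, final: LandCoverGrid) -> ChangeCodeGrid:
    """Code the three modelled transitions between two maps of the same extent."""
    if initial.shape != final.shape:
        raise GridError(
            f"change_code: shape mismatch {initial.shape} vs {final.shape}"
        )
    a, b = initial.cells, final.cells
    codes = np.zeros(a.shape, dtype=np.int8)
    codes[(a == FOREST) & (b == DEFORESTED)] = CODE_FTOD
    codes[(a == REGEN) & (b == DEFORESTED)] = CODE_RTOD
    codes[(a == DEFORESTED) & (b == REGEN)] = CODE_DTOR
    codes[(a == NODATA) | (b == NODATA)] = CODE_NODATA
    return ChangeCodeGrid(codes, initial.year, final.year)


def perfect_match(
    observed: ChangeCodeGrid, predicted: Sequence[ChangeCodeGrid]
) -> PerfectMatchResult:
    """Mean percentage of observed changed cells predicted exactly.

    ``predicted`` holds one change-code grid per stochastic iteration; the
    result carries the per-iteration percentages and their arithmetic mean.
    Raises if the observed grid contains no change (the metric divides by
    the amount of observed change).
    """
    obs = observed.codes
    changed = obs > 0
    n_obs = int(np.count_nonzero(changed))
    if n_obs == 0:
        raise ValueError(
            "perfect_match: observed change grid has no changed cells "
            "(total amount of observed change is zero)"
        )
    pct = np.empty(len(predicted))
    for i, pred in enumerate(predicted):
        if pred.codes.shape != obs.shape:
            raise GridError("perfect_match: predicted grid shape mismatch")
        hits = np.count_nonzero(changed & (pred.codes == obs))
        pct[i] = 100.0 * hits / n_obs
    return PerfectMatchResult(per_iteration=pct, mean=float(pct.mean()), n_observed_changes=n_obs)
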