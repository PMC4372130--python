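"""Forward stochastic simulation of land-cover change.

Each simulation iteration draws one joint coefficient row per transition
from its posterior sample, then advances the landscape in steps of one
transition interval (n years).  Within a step all three transitions are
applied synchronously to the incoming map: every forest cell flips to
deforested with probability P_FtoD, every regeneration cell to deforested
with P_RtoD and every deforested cell to regeneration with P_DtoR, by
independent uniform draws.  Dynamic covariates (contagion, land-use
history) are recomputed from the simulated trajectory between steps, so
change begets change — the contagion mechanism.  Repeating the whole run
for many iterations (default 100) with fresh posterior draws yields
prediction envelopes that carry the parameter uncertainty forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import (
    CovariateStack,
    _history_from_grids,
    compute_static_layers,
    contagion,
)
from .grids import (
    DEFORESTED,
    FOREST,
    NODATA,
    REGEN,
    FeatureLayers,
    LandCoverGrid,
    LandCoverSeries,
)
from .model import FitResult, TransitionKind, kappa, transition_probability


@dataclass
class SimulationConfig:
    """Settings for one batch of stochastic simulations."""

    n_iterations: int = 100
    transition_length: int = 1
    n_steps: int = 1
    seed: int = 0
    radius: int = 1

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_steps < 1 or self.transition_length < 1:
            raise ValueError("n_iterations, n_steps and transition_length must be >= 1")

    def predicted_years(self, start_year: int) -> list[int]:
        return [start_year + k * self.transition_length for k in range(1, self.n_steps + 1)]


@dataclass
class SimulationOutput:
    """Per-iteration predicted maps, mean probability grids and event counts."""

    start_year: int
    years: list[int]                        # predicted years, one per step
    maps: list[list[LandCoverGrid]]         # [iteration][step]
    prob_defor: list[np.ndarray]            # per-step mean P(deforestation) grid
    prob_regen: list[np.ndarray]            # per-step mean P(regeneration) grid
    change_rates: pd.DataFrame              # iteration, step, year, transition, count

    def maps_for_year(self, year: int) -> list[LandCoverGrid]:
        idx = self.years.index(year)
        return [it_maps[idx] for it_maps in self.maps]

    def counts(self, transition: TransitionKind, step: int) -> np.ndarray:
        df = self.change_rates
        sel = (df["transition"] == transition.label) & (df["step"] == step)
        return df.loc[sel].sort_values("iteration")["count"].to_numpy()


def _dynamic_stack(
    current: LandCoverGrid,
    history_grids: Sequence[LandCoverGrid],
    static: Mapping[str, np.ndarray],
    radius: int,
) -> CovariateStack:
    """Stack for the incoming map: cached statics + freshly recomputed dynamics."""
    layers = dict(static)
    layers["contagion_defor"] = contagion(current, DEFORESTED, radius)
    layers["contagion_regen"] = contagion(current, REGEN, radius)
    palu, arf, fc = _history_from_grids(
        [g.cells for g in history_grids], [g.year for g in history_grids], current.year
    )
    layers.update(palu=palu, arf=arf, fc=fc)
    return CovariateStack(current.year, layers, current.valid_mask, current.cell_size)


def step(
    current: LandCoverGrid,
    fits: Mapping[TransitionKind, FitResult | None],
    coefficients: Mapping[TransitionKind, np.ndarray | None],
    features: FeatureLayers | None,
    history_grids: Sequence[LandCoverGrid],
    rng: np.random.Generator,
    radius: int = 1,
    static: Mapping[str, np.ndarray] | None = None,
    next_year: int | None = None,
) -> tuple[LandCoverGrid, dict[str, int]]:
    """Advance the landscape by one transition interval (synchronous update).

    All Bernoulli draws see the incoming map; covariates are recomputed
    from it before any cell changes, so within-step updates cannot cascade.
    ``history_grids`` is the trajectory up to and including ``current`` and
    feeds the land-use history covariates.  Transitions whose fit is None
    are frozen (probability 0).  Returns the new map and realised event
    counts; NODATA cells never change state.
    """
    new_grid, counts, _ = _step_impl(
        current, fits, coefficients, features, history_grids, rng, radius,
        static, next_year,
    )
    return new_grid, counts


def _step_impl(
    current,
    fits,
    coefficients,
    features,
    history_grids,
    rng,
    radius,
    static,
    next_year,
):
    if static is None:
        if features is None:
            raise ValueError("step needs either feature layers or cached statics")
        static = compute_static_layers(features, current.cell_size)
    stack = _dynamic_stack(current, history_grids, static, radius)

    cells_flat = current.cells.ravel()
    new_flat = cells_flat.copy()
    counts: dict[str, int] = {}
    probs: dict[TransitionKind, tuple[np.ndarray, np.ndarray]] = {}
    for kind in TransitionKind:
        fit = fits.get(kind)
        source_idx = np.flatnonzero(cells_flat == kind.source_state)
        if fit is None or source_idx.size == 0:
            counts[kind.label] = 0
            continue
        P = transition_probability(
            kappa(fit.spec, coefficients[kind], stack, source_idx)
        )
        probs[kind] = (source_idx, P)
        u = rng.random(source_idx.size)
        flip = source_idx[u < P]
        new_flat[flip] = kind.target_state
        counts[kind.label] = int(flip.size)
    year = current.year + 1 if next_year is None else next_year
    new_grid = current.with_cells(new_flat.reshape(current.shape), year=year)
    return new_grid, counts, probs


def simulate(
    initial: LandCoverGrid,
    fits: Mapping[TransitionKind, FitResult | None],
    features: FeatureLayers,
    history: LandCoverSeries | Sequence[LandCoverGrid],
    config: SimulationConfig,
) -> SimulationOutput:
    """Run ``config.n_iterations`` independent stochastic trajectories.

    Each iteration owns an RNG stream derived from (seed, iteration), so
    runs are reproducible and individual iterations can be re-run in
    isolation.  ``history`` (a series or plain grid list) must contain
    ``initial.year``; simulated maps are appended to a copy of it as the
    trajectory grows, keeping the land-use history metrics consistent with
    the calibration convention.
    """
    history_grids = history.grids if isinstance(history, LandCoverSeries) else list(history)
    if initial.year not in [g.year for g in history_grids]:
        raise ValueError(
            f"history series must contain the initial year {initial.year}"
        )
    for kind, fit in fits.items():
        if fit is not None and fit.posterior.samples.shape[0] == 0:
            raise ValueError(f"{kind.label}: posterior has no samples")

    static = compute_static_layers(features, initial.cell_size)
    years = config.predicted_years(initial.year)
    base_history = [g for g in history_grids if g.year <= initial.year]

    all_maps: list[list[LandCoverGrid]] = []
    rows = []
    shape = initial.shape
    prob_defor_sum = [np.zeros(shape) for _ in years]
    prob_regen_sum = [np.zeros(shape) for _ in years]

    for it in range(config.n_iterations):
        rng = np.random.default_rng([config.seed, it])
        coefs = {
            kind: (fit.posterior.draw_row(rng) if fit is not None else None)
            for kind, fit in fits.items()
        }
        trajectory = list(base_history)
        current = initial
        it_maps: list[LandCoverGrid] = []
        for k, year in enumerate(years):
            new_grid, counts, probs = _step_impl(
                current, fits, coefs, features, trajectory, rng,
                config.radius, static, year,
            )
            for kind, (idx, P) in probs.items():
                target = (
                    prob_regen_sum[k] if kind is TransitionKind.DtoR else prob_defor_sum[k]
                )
                np.add.at(target.ravel(), idx, P)
            trajectory.append(new_grid)
            it_maps.append(new_grid)
            for label, cnt in counts.items():
                rows.append(
                    {"iteration": it, "step": k + 1, "year": year,
                     "transition": label, "count": cnt}
                )
            current = new_grid
        all_maps.append(it_maps)

    n = config.n_iterations
    return SimulationOutput(
        start_year=initial.year,
        years=years,
        maps=all_maps,
        prob_defor=[s / n for s in prob_defor_sum],
        prob_regen=[s / n for s in prob_regen_sum],
        change_rates=pd.DataFrame(
            rows, columns=["iteration", "step", "year", "transition", "count"]
        ),
    )


def write_change_rates(output: SimulationOutput, path: str | Path) -> Path:
    path = Path(path)
    output.change_rates.to_csv(path, index=False)
    return path
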