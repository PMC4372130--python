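"""Synthetic landscapes with the statistical structure the models assume.

The generator builds a rectangular landscape with parametric driver
geometry — two road polylines crossing the grid, one river, one
settlement point, one rectangular protected area covering about a quarter
of the landscape, and a small water body acting as a shared nodata mask —
and then simulates land cover forward *annually* from known transition
coefficients through the exact logistic/contagion machinery used for
fitting.  Grids are recorded only at the requested observation years, so
downstream code faces realistic gaps between dates.  Because the
generative process and the fitted model share one likelihood, parameter
recovery and posterior-predictive checks are well-posed by construction.

True coefficients may be scalars or piecewise-linear functions of the
calendar year (given as {year: value} breakpoints), which is how
time-varying drivers — e.g. a protected-area effect that strengthens over
the study period — are injected for the calibration-window experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

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
    GridError,
    LandCoverGrid,
    LandCoverSeries,
)
from .model import TransitionKind, kappa, transition_probability, PredictorSpec

#: Coefficient value: a constant, or {year: value} breakpoints interpolated
#: piecewise-linearly (and held constant beyond the first/last breakpoint).
CoefValue = float | Mapping[int, float]

#: Default observation calendar: 20 dates over 1986-2011 with gaps, the
#: cadence of a Landsat-derived land-cover archive.
DEFAULT_YEARS: tuple[int, ...] = (
    1986, 1987, 1989, 1991, 1992, 1994, 1995, 1996, 1997, 1999,
    2001, 2002, 2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011,
)

#: Default annual-scale truth.  Magnitudes follow the field's reporting
#: conventions for 30 m landscapes: contagion coefficients of order 1,
#: distance coefficients of order 1e-4 per metre, protection terms of
#: order 1.  Intercepts are set so the landscape loses forest at a few
#: percent per year near drivers while staying quiet far from them.
DEFAULT_TRUTH: dict[TransitionKind, dict[str, CoefValue]] = {
    TransitionKind.FtoD: {
        "intercept": -3.5,
        "contagion_defor": 4.0,
        "dist_roads": -0.00056,
        "protected": -1.5,
    },
    TransitionKind.RtoD: {
        "intercept": -2.5,
        "contagion_defor": 1.2,
        "dist_roads": -0.00016,
        "protected": -0.4,
    },
    TransitionKind.DtoR: {
        "intercept": -2.5,
        "contagion_regen": 1.5,
        "dist_roads": 0.00035,
        "protected": 0.15,
    },
}


@dataclass
class SyntheticScenario:
    """Everything needed to generate one synthetic landscape history."""

    shape: tuple[int, int] = (100, 100)
    seed: int = 0
    years: tuple[int, ...] = DEFAULT_YEARS
    truth: Mapping[TransitionKind, Mapping[str, CoefValue]] = field(
        default_factory=lambda: DEFAULT_TRUTH
    )
    cell_size: float = 30.0
    radius: int = 1
    n_nuclei: int = 3
    nucleus_radius: int = 3
    n_regen_patches: int = 0
    regen_patch_radius: int = 4
    water_fraction: float = 0.02
    features: FeatureLayers | None = None

    def __post_init__(self) -> None:
        self.years = tuple(sorted(int(y) for y in self.years))
        if len(self.years) < 2:
            raise ValueError("scenario needs at least two observation years")
        if self.features is None:
            self.features = make_features(self.shape, self.seed)


def _polyline_cells(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a polyline (Bresenham per segment) into a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(points, points[1:]):
        n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    return mask


def make_features(shape: tuple[int, int], seed: int) -> FeatureLayers:
    """Parametric driver geometry: 2 roads, 1 river, 1 settlement, 1 reserve.

    Deterministic given the seed.  Requires a grid of at least 50x50 so
    the geometry does not degenerate.
    """
    nr, nc = shape
    if nr < 50 or nc < 50:
        raise GridError(f"feature generation needs a grid >= 50x50, got {shape}")
    rng = np.random.default_rng(seed)

    def crossing_polyline(vertical: bool) -> np.ndarray:
        # three-point polyline spanning the grid with a jittered midpoint
        if vertical:
            c0, c1 = rng.integers(5, nc - 5, size=2)
            mid = ((nr - 1) / 2 + rng.integers(-nr // 6, nr // 6),
                   (c0 + c1) / 2 + rng.integers(-nc // 6, nc // 6))
            return np.array([(0, c0), mid, (nr - 1, c1)], dtype=float)
        r0, r1 = rng.integers(5, nr - 5, size=2)
        mid = ((r0 + r1) / 2 + rng.integers(-nr // 6, nr // 6),
               (nc - 1) / 2 + rng.integers(-nc // 6, nc // 6))
        return np.array([(r0, 0), mid, (r1, nc - 1)], dtype=float)

    roads = _polyline_cells(crossing_polyline(True), shape)
    roads |= _polyline_cells(crossing_polyline(False), shape)
    rivers = _polyline_cells(crossing_polyline(bool(rng.integers(2))), shape)

    settlements = np.zeros(shape, dtype=bool)
    # settlement placed on (or next to) a road, as settlements are
    road_cells = np.argwhere(roads)
    sr, sc = road_cells[rng.integers(len(road_cells))]
    settlements[sr, sc] = True

    # protected rectangle with area fraction drawn in [0.2, 0.3]
    frac = rng.uniform(0.2, 0.3)
    h = int(round(np.sqrt(frac * nr * nc * nr / nc)))
    w = int(round(frac * nr * nc / max(h, 1)))
    h, w = min(h, nr), min(w, nc)
    r0 = int(rng.integers(0, nr - h + 1))
    c0 = int(rng.integers(0, nc - w + 1))
    protected = np.zeros(shape, dtype=bool)
    protected[r0 : r0 + h, c0 : c0 + w] = True

    return FeatureLayers(roads, rivers, settlements, protected)


def _disc(shape: tuple[int, int], centre: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def _initial_state(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """All forest, seeded deforested nuclei near roads, optional regen patches,
    and a water blob applied as NODATA."""
    nr, nc = scenario.shape
    cells = np.full(scenario.shape, FOREST, dtype=np.int8)
    road_cells = np.argwhere(scenario.features.roads)
    for _ in range(scenario.n_nuclei):
        r, c = road_cells[rng.integers(len(road_cells))]
        cells[_disc(scenario.shape, (int(r), int(c)), scenario.nucleus_radius)] = DEFORESTED
    for _ in range(scenario.n_regen_patches):
        r, c = rng.integers(0, nr), rng.integers(0, nc)
        cells[_disc(scenario.shape, (int(r), int(c)), scenario.regen_patch_radius)] = REGEN
    if scenario.water_fraction > 0:
        water_radius = int(np.sqrt(scenario.water_fraction * nr * nc / np.pi))
        r, c = rng.integers(nr // 8, nr - nr // 8), rng.integers(nc // 8, nc - nc // 8)
        cells[_disc(scenario.shape, (int(r), int(c)), max(water_radius, 1))] = NODATA
    return cells


def _coef_at(value: CoefValue, year: int) -> float:
    if isinstance(value, Mapping):
        pts = sorted(value.items())
        xs = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts], dtype=float)
        return float(np.interp(year, xs, ys))
    return float(value)


def truth_coefficients(
    truth: Mapping[TransitionKind, Mapping[str, CoefValue]],
    kind: TransitionKind,
    year: int,
) -> tuple[PredictorSpec, np.ndarray]:
    """Resolve one transition's true predictor spec and coefficient vector."""
    terms = truth.get(kind)
    if terms is None:
        return PredictorSpec(kind, ()), np.array([-np.inf])
    names = tuple(n for n in terms if n != "intercept")
    spec = PredictorSpec(kind, names)
    coefs = np.array(
        [_coef_at(terms.get("intercept", 0.0), year)]
        + [_coef_at(terms[n], year) for n in names]
    )
    return spec, coefs


def generate_truth_series(scenario: SyntheticScenario) -> LandCoverSeries:
    """Simulate the landscape annually from known coefficients; record at
    the scenario's observation years.

    The annual update is exactly the simulator's synchronous step: per
    source-class cell a logistic probability from the true (possibly
    time-varying) coefficients, then an independent uniform draw.
    Deterministic given the scenario seed.  Warns if the whole horizon
    produces no transition events (an untestable scenario).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    features = scenario.features
    static = compute_static_layers(features, scenario.cell_size)
    years = scenario.years
    cells = _initial_state(scenario, rng)

    trajectory_cells = [cells]
    trajectory_years = [years[0]]
    observed: list[LandCoverGrid] = []
    if years[0] in scenario.years:
        observed.append(LandCoverGrid(years[0], cells.copy(), scenario.cell_size))

    n_events = 0
    for year in range(years[0], years[-1]):
        layers = dict(static)
        layers["contagion_defor"] = contagion(cells, DEFORESTED, scenario.radius)
        layers["contagion_regen"] = contagion(cells, REGEN, scenario.radius)
        palu, arf, fc = _history_from_grids(trajectory_cells, trajectory_years, year)
        layers.update(palu=palu, arf=arf, fc=fc)
        stack = CovariateStack(year, layers, cells != NODATA, scenario.cell_size)

        flat = cells.ravel()
        new_flat = flat.copy()
        for kind in TransitionKind:
            spec, coefs = truth_coefficients(scenario.truth, kind, year)
            idx = np.flatnonzero(flat == kind.source_state)
            if idx.size == 0 or not np.isfinite(coefs[0]):
                continue
            P = transition_probability(kappa(spec, coefs, stack, idx))
            flip = idx[rng.random(idx.size) < P]
            new_flat[flip] = kind.target_state
            n_events += flip.size
        cells = new_flat.reshape(scenario.shape)
        trajectory_cells.append(cells)
        trajectory_years.append(year + 1)
        if (year + 1) in scenario.years:
            observed.append(LandCoverGrid(year + 1, cells.copy(), scenario.cell_size))

    if n_events == 0:
        import warnings

        warnings.warn(
            "synthetic truth produced no land-cover change over the whole "
            "horizon; the scenario is untestable",
            RuntimeWarning,
        )
    from .grids import build_series

    return build_series(observed)
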