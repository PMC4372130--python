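"""Calibration-window experiments and temporal trend analyses.

Two meta-analyses sit on top of the fit/simulate/validate pipeline:

1. **Calibration-window design grid.** A model design is a pair of map
   years (start, end); its transition length is end - start, and it can
   predict exactly the years end + k*length.  All designs whose predicted
   sequence lands on a target year are enumerated, each is fitted by
   stepwise selection, simulated forward, and validated by perfect match
   against every available later map its sequence hits.  A sequential
   (Type I) ANOVA then decomposes the perfect-match results into the
   effects of initial year, transition length, time step and validation
   year (all treated as numeric covariates, 1 df each) and their
   interactions.  The transition-length x time-step product is excluded:
   by the design arithmetic step*length = validation - initial - length,
   so that term is an exact linear combination of the others.

2. **Univariate parameter series.** For every adjacent pair of map dates,
   each single-covariate model is refitted, giving a time series of
   posterior means whose temporal trend is tested by ordinary least
   squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import assemble_stack, compute_static_layers
from .grids import FeatureLayers, LandCoverSeries, NODATA, DEFORESTED, FOREST, REGEN
from .model import (
    ChainConfig,
    PredictorSpec,
    TransitionKind,
    calibration_data,
    fit_mcmc,
    fit_transition,
)
from .simulate import SimulationConfig, simulate
from .validate import change_code, perfect_match


@dataclass(frozen=True)
class ModelDesign:
    """A calibration pair (start_year, end_year) and its prediction arithmetic."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")

    @property
    def transition_length(self) -> int:
        return self.end_year - self.start_year

    def predicted_years(self, last_year: int) -> list[int]:
        """The arithmetic sequence start + k*length, up to last_year.

        The model steps forward from the start-year map, so its first
        prediction is the calibration end year itself (step 1) — that is
        how a 1991-1995 design reaches 2011 as its 5th step.
        """
        n = self.transition_length
        return list(range(self.start_year + n, last_year + 1, n))

    def time_step_of(self, target_year: int) -> int:
        """Step index of target_year, counting the calibration end year as 1."""
        n = self.transition_length
        if target_year <= self.start_year or (target_year - self.start_year) % n:
            raise ValueError(
                f"design {self.start_year}-{self.end_year} never predicts {target_year}"
            )
        return (target_year - self.start_year) // n


@dataclass
class TrendResult:
    """Simple-regression trend summary (df = n - 2)."""

    slope: float
    t_statistic: float
    r_squared: float
    degrees_freedom: int
    p_value: float
    intercept: float = float("nan")


def enumerate_designs(
    available_years: Sequence[int], target_year: int
) -> list[ModelDesign]:
    """All calibration pairs whose prediction sequence lands on target_year.

    A pair (start, end) of available map years qualifies when end precedes
    the target and stepping from end in increments of (end - start) lands
    exactly on the target — e.g. with annual maps, 1991-1995 reaches 2011
    as its 5th step, while 1991-1997 (predicting 2003, 2009, ...) never
    does.
    """
    years = sorted(set(int(y) for y in available_years))
    if not years:
        raise ValueError("no available map years")
    if target_year <= min(years):
        raise ValueError("target year must follow the earliest available map")
    designs = []
    for start, end in itertools.combinations(years, 2):
        if end >= target_year:
            continue
        if (target_year - start) % (end - start) == 0:
            designs.append(ModelDesign(start, end))
    return designs


def validation_years(
    design: ModelDesign, available_years: Sequence[int], last_year: int
) -> list[int]:
    """Available map years after the calibration pair that the design's
    prediction sequence hits, up to last_year."""
    available = set(int(y) for y in available_years)
    return [
        y for y in design.predicted_years(last_year)
        if y in available and y > design.end_year
    ]


def run_design_grid(
    series: LandCoverSeries,
    features: FeatureLayers,
    designs: Sequence[ModelDesign],
    chain: ChainConfig | None = None,
    sim: SimulationConfig | None = None,
    candidates: Mapping[TransitionKind, Sequence[str]] | None = None,
    transitions: Sequence[TransitionKind] = tuple(TransitionKind),
    last_year: int | None = None,
    radius: int = 1,
) -> pd.DataFrame:
    """Fit, simulate and validate every design; one row per validation year.

    Per design: stepwise selection per modelled transition on the
    calibration pair, forward simulation from the end-year map to the last
    predicted year, and perfect match against each available later map the
    prediction sequence hits.  Transitions not listed in ``transitions``
    are frozen in the simulation.  Columns: initial_year,
    transition_length, time_step, validation_year, perfect_match.
    """
    if not designs:
        raise ValueError("no designs to run")
    chain = chain or ChainConfig()
    sim = sim or SimulationConfig()
    last_year = max(series.years) if last_year is None else last_year
    static = compute_static_layers(features, series.cell_size)

    rows = []
    for d_idx, design in enumerate(designs):
        try:
            vyears = validation_years(design, series.years, last_year)
            if not vyears:
                continue
            fits: dict[TransitionKind, object] = {k: None for k in TransitionKind}
            for t_idx, kind in enumerate(transitions):
                cand = None if candidates is None else list(candidates[kind])
                seed = (chain.seed * 1_000_003 + d_idx * 17 + t_idx) % (2**31)
                fit, _ = fit_transition(
                    series, features, design.start_year, design.end_year, kind,
                    candidates=cand, chain=chain.replace(seed=seed),
                    split_seed=seed + 1, radius=radius, static=static,
                )
                fits[kind] = fit
            n_steps = design.time_step_of(max(vyears))
            config = SimulationConfig(
                n_iterations=sim.n_iterations,
                transition_length=design.transition_length,
                n_steps=n_steps,
                seed=(sim.seed * 1_000_003 + d_idx) % (2**31),
                radius=radius,
            )
            # the model steps forward from the calibration start-year map,
            # so the calibration end year is its first predicted step
            initial = series.grid_for(design.start_year)
            history = [g for g in series.grids if g.year <= design.start_year]
            output = simulate(initial, fits, features, history, config)
            for vy in vyears:
                observed = change_code(initial, series.grid_for(vy))
                predicted = [change_code(initial, m) for m in output.maps_for_year(vy)]
                pm = perfect_match(observed, predicted)
                rows.append(
                    {
                        "initial_year": design.start_year,
                        "end_year": design.end_year,
                        "transition_length": design.transition_length,
                        "time_step": design.time_step_of(vy),
                        "validation_year": vy,
                        "perfect_match": pm.mean,
                        "n_observed_changes": pm.n_observed_changes,
                    }
                )
        except Exception as exc:
            raise RuntimeError(
                f"design {design.start_year}-{design.end_year} failed: {exc}"
            ) from exc
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequential ANOVA of the design-grid results

_ANOVA_FACTORS = {
    "Initial year": ("initial_year",),
    "Transition length": ("transition_length",),
    "Time step": ("time_step",),
    "Validation year": ("validation_year",),
}

#: Term order of the decomposition: main effects, then interactions.  The
#: transition-length x time-step product is structurally collinear with
#: {validation year, initial year, transition length} and is omitted.
ANOVA_TERMS: list[tuple[str, tuple[str, ...]]] = [
    ("Initial year", ("initial_year",)),
    ("Transition length", ("transition_length",)),
    ("Time step", ("time_step",)),
    ("Validation year", ("validation_year",)),
    ("Initial year x Transition length", ("initial_year", "transition_length")),
    ("Initial year x Time step", ("initial_year", "time_step")),
    ("Initial year x Validation year", ("initial_year", "validation_year")),
    ("Transition length x Validation year", ("transition_length", "validation_year")),
    ("Time step x Validation year", ("time_step", "validation_year")),
    ("Initial year x Transition length x Time step",
     ("initial_year", "transition_length", "time_step")),
    ("Initial year x Transition length x Validation year",
     ("initial_year", "transition_length", "validation_year")),
    ("Initial year x Time step x Validation year",
     ("initial_year", "time_step", "validation_year")),
    ("Transition length x Time step x Validation year",
     ("transition_length", "time_step", "validation_year")),
    ("Initial year x Transition length x Time step x Validation year",
     ("initial_year", "transition_length", "time_step", "validation_year")),
]


def anova_decomposition(
    results: pd.DataFrame, response: str = "perfect_match"
) -> pd.DataFrame:
    """Sequential (Type I) sums of squares over the four design factors.

    Factors enter as numeric covariates (1 df per term) in the fixed
    term order of :data:`ANOVA_TERMS`; each term's SS is the drop in
    residual SS when its product column joins the regression.  Returns a
    table with term, df, sum_sq, mean_sq, F and p rows plus a Residuals
    row; the term SS and residual SS add up to the total SS about the
    mean.  Raises if a term's column is collinear with what precedes it.
    """
    for col in ("initial_year", "transition_length", "time_step", "validation_year"):
        if col not in results.columns:
            raise ValueError(f"results table missing column {col!r}")
        if results[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 distinct values")
    y = results[response].to_numpy(dtype=np.float64)
    n = y.size
    # factors are centred before products are formed: calendar-year-scale
    # raw products are too ill-conditioned for a meaningful decomposition
    centred = {
        f: results[f].to_numpy(dtype=np.float64) - results[f].mean()
        for f in ("initial_year", "transition_length", "time_step", "validation_year")
    }
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    total_ss = rss_prev
    entries = []
    for term_name, factors in ANOVA_TERMS:
        col = np.ones(n)
        for f in factors:
            col = col * centred[f]
        proj, _, _, _ = np.linalg.lstsq(X, col, rcond=None)
        resid_col = col - X @ proj
        if np.linalg.norm(resid_col) < 1e-8 * max(np.linalg.norm(col), 1e-30):
            raise ValueError(
                f"ANOVA term {term_name!r} is collinear with preceding terms"
            )
        X_new = np.column_stack([X, col])
        beta, _, _, _ = np.linalg.lstsq(X_new, y, rcond=None)
        rss = float(np.sum((y - X_new @ beta) ** 2))
        entries.append((term_name, rss_prev - rss))
        X, rss_prev = X_new, rss
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    rows = []
    for term_name, ss in entries:
        F = ss / ms_resid if ms_resid > 0 else np.inf
        p = float(stats.f.sf(F, 1, df_resid))
        rows.append({"term": term_name, "df": 1, "sum_sq": ss,
                     "mean_sq": ss, "F": F, "p": p})
    rows.append({"term": "Residuals", "df": df_resid, "sum_sq": rss_prev,
                 "mean_sq": ms_resid, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows)
    table.attrs["total_ss"] = total_ss
    return table


# ---------------------------------------------------------------------------
# Univariate parameter series and trend tests


def univariate_parameter_series(
    series: LandCoverSeries,
    features: FeatureLayers,
    covariate: str,
    transition: TransitionKind,
    chain: ChainConfig | None = None,
    radius: int = 1,
) -> pd.DataFrame:
    """Single-covariate coefficient refitted on every adjacent date pair.

    Returns one row per interval: start_year, end_year, posterior mean and
    the 95% credible bounds of the covariate's coefficient.  This is the
    raw material for the temporal trend tests.
    """
    years = series.years
    if len(years) < 3:
        raise ValueError(
            "cannot form a parameter series from a single interval; "
            "need at least three map dates"
        )
    chain = chain or ChainConfig()
    static = compute_static_layers(features, series.cell_size)
    spec = PredictorSpec(transition, (covariate,))
    rows = []
    for i, (y0, y1) in enumerate(zip(years, years[1:])):
        start, end = series.grid_for(y0), series.grid_for(y1)
        cells, Z = calibration_data(start, end, transition)
        if cells.size == 0:
            raise ValueError(
                f"interval {y0}-{y1} has no {transition.label} source-class cells"
            )
        stack = assemble_stack(start, series, features, year=y0, radius=radius,
                               static=static)
        post = fit_mcmc(
            spec, Z, stack, cells,
            chain.replace(seed=(chain.seed * 1_000_003 + i) % (2**31)),
        )
        rows.append(
            {
                "start_year": y0,
                "end_year": y1,
                "transition": transition.label,
                "covariate": covariate,
                "mean": post.mean[1],
                "ci_low": post.ci95[1, 0],
                "ci_high": post.ci95[1, 1],
                "n_cells": cells.size,
            }
        )
    return pd.DataFrame(rows)


def trend_test(values: Sequence[float], predictor: Sequence[float]) -> TrendResult:
    """Ordinary least squares of values on a predictor (years or rates)."""
    values = np.asarray(values, dtype=np.float64)
    predictor = np.asarray(predictor, dtype=np.float64)
    if values.size != predictor.size:
        raise ValueError("values and predictor lengths differ")
    if values.size < 3:
        raise ValueError("trend test needs at least 3 points")
    if np.ptp(predictor) == 0:
        raise ValueError("trend predictor has zero variance")
    if np.ptp(values) == 0:
        # constant response: flat line, no trend
        return TrendResult(0.0, 0.0, 0.0, values.size - 2, 1.0, float(values[0]))
    res = stats.linregress(predictor, values)
    n = values.size
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return TrendResult(
        slope=float(res.slope),
        t_statistic=float(t),
        r_squared=float(res.rvalue**2),
        degrees_freedom=n - 2,
        p_value=float(res.pvalue),
        intercept=float(res.intercept),
    )


def landscape_composition(
    series: LandCoverSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class proportions per map date and annualised transition rates per interval.

    Proportions are over valid (non-NODATA) cells and sum to one per year.
    The per-interval rate of a transition is the count of source-class
    cells that made it, divided by the source-class count at the interval
    start and by the interval length in years.
    """
    prop_rows = []
    for g in series.grids:
        valid = g.valid_mask
        nv = int(valid.sum())
        prop_rows.append(
            {
                "year": g.year,
                "forest": float(np.count_nonzero(g.cells == FOREST)) / nv,
                "regeneration": float(np.count_nonzero(g.cells == REGEN)) / nv,
                "deforested": float(np.count_nonzero(g.cells == DEFORESTED)) / nv,
            }
        )
    rate_rows = []
    for g0, g1 in zip(series.grids, series.grids[1:]):
        span = g1.year - g0.year
        for kind in TransitionKind:
            source = g0.cells == kind.source_state
            n_source = int(np.count_nonzero(source))
            events = int(np.count_nonzero(source & (g1.cells == kind.target_state)))
            rate = events / n_source / span if n_source else np.nan
            rate_rows.append(
                {
                    "start_year": g0.year,
                    "end_year": g1.year,
                    "transition": kind.label,
                    "events": events,
                    "n_source": n_source,
                    "rate_per_year": rate,
                }
            )
    return pd.DataFrame(prop_rows), pd.DataFrame(rate_rows)
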