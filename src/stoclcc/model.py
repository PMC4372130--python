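"""Per-pixel logistic transition models, MCMC fitting and stepwise selection.

Three land-cover transitions are modelled independently: forest to
deforested (FtoD), regeneration to deforested (RtoD) and deforested to
regeneration (DtoR).  For a source-class cell x the probability of making
the transition over one time interval is the logistic

    P_x = 1 / (1 + exp(-kappa_x)),    kappa_x = b0 + sum_j b_j * c_j(x),

with c_j the covariate layers.  The Bernoulli log-likelihood over cells,

    ll = sum_x log[ Z_x P_x + (1 - Z_x)(1 - P_x) ],

is sampled with a componentwise random-walk Metropolis algorithm under a
flat box prior, giving a coefficient posterior (mean and central 95%
credible interval) from which the simulator later draws joint rows.

Covariate selection is forward stepwise: starting from the intercept-only
model, each remaining candidate is tentatively added, the model is fitted
on a random half of the source cells, and the addition with the best
log-likelihood on the held-out half is kept; selection stops when no
addition improves the held-out likelihood.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .covariates import CovariateStack, HISTORY_LAYERS, LAYER_NAMES
from .grids import DEFORESTED, FOREST, NODATA, REGEN, LandCoverGrid

_PROB_EPS = 1e-12


class TransitionKind(enum.Enum):
    """The three modelled transitions; each fixes source and target classes."""

    FtoD = ("FtoD", FOREST, DEFORESTED)
    RtoD = ("RtoD", REGEN, DEFORESTED)
    DtoR = ("DtoR", DEFORESTED, REGEN)

    def __init__(self, label: str, source: int, target: int):
        self.label = label
        self.source_state = source
        self.target_state = target

    @property
    def third_state(self) -> int:
        return ({DEFORESTED, FOREST, REGEN} - {self.source_state, self.target_state}).pop()

    def candidate_layers(self) -> tuple[str, ...]:
        """Layers admissible for this transition (history metrics: RtoD only)."""
        if self is TransitionKind.RtoD:
            return LAYER_NAMES
        return tuple(n for n in LAYER_NAMES if n not in HISTORY_LAYERS)


@dataclass(frozen=True)
class PredictorSpec:
    """A linear predictor: an always-included intercept plus named covariates."""

    transition: TransitionKind
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.covariate_names)
        object.__setattr__(self, "covariate_names", names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariates in spec: {names}")
        allowed = self.transition.candidate_layers()
        for n in names:
            if n not in LAYER_NAMES:
                raise ValueError(f"unknown covariate {n!r}")
            if n not in allowed:
                raise ValueError(
                    f"covariate {n!r} not admissible for {self.transition.label} "
                    "(history metrics apply to RtoD only)"
                )

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.covariate_names

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.covariate_names)


@dataclass
class CoefficientPosterior:
    """Retained MCMC draws plus their summaries, on the raw covariate scale."""

    names: tuple[str, ...]
    samples: np.ndarray          # (n_retained, n_coefficients)
    mean: np.ndarray
    ci95: np.ndarray             # (n_coefficients, 2): 2.5 and 97.5 percentiles
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.names):
            raise ValueError("posterior sample matrix shape inconsistent with names")
        if self.samples.shape[0] < 100:
            raise ValueError(
                f"posterior needs >= 100 retained samples, got {self.samples.shape[0]}"
            )

    def draw_row(self, rng: np.random.Generator) -> np.ndarray:
        """One joint coefficient vector, sampled uniformly from retained draws."""
        return self.samples[rng.integers(self.samples.shape[0])]


@dataclass
class ChainConfig:
    """Random-walk Metropolis settings.

    Defaults: 20,000 sweeps, the first half discarded as burn-in, thinned
    to about 1,000 retained draws; proposal step sizes adapt
    per-coefficient during burn-in only.
    """

    iterations: int = 20_000
    burn_in: float = 0.5
    n_retain: int = 1_000
    seed: int = 0
    prior_bound: float = 50.0
    init_step: float = 0.2
    adapt_interval: int = 50

    def replace(self, **kw) -> "ChainConfig":
        import dataclasses

        return dataclasses.replace(self, **kw)


@dataclass
class FitResult:
    """Selected predictor, its posterior, and the split log-likelihoods (nats)."""

    spec: PredictorSpec
    posterior: CoefficientPosterior
    train_ll: float
    test_ll: float
    split_seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "transition": self.spec.transition.label,
            "covariates": list(self.spec.covariate_names),
            "coefficient_names": list(self.posterior.names),
            "posterior_mean": self.posterior.mean.tolist(),
            "ci95": self.posterior.ci95.tolist(),
            "train_ll": self.train_ll,
            "test_ll": self.test_ll,
            "split_seed": self.split_seed,
            "acceptance_rate": self.posterior.acceptance_rate,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# Linear predictor, probability, likelihood


def design_matrix(
    spec: PredictorSpec, stack: CovariateStack, cells: np.ndarray
) -> np.ndarray:
    """Covariate matrix (n_cells, n_covariates) at flat cell indices."""
    cols = [stack.layer(n).ravel()[cells] for n in spec.covariate_names]
    if not cols:
        return np.empty((cells.size, 0))
    return np.column_stack(cols)


def kappa(
    spec: PredictorSpec,
    coefficients: np.ndarray,
    stack: CovariateStack,
    cells: np.ndarray,
) -> np.ndarray:
    """Linear predictor kappa = b0 + X b at the given cells."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.size != spec.n_coefficients:
        raise ValueError(
            f"expected {spec.n_coefficients} coefficients, got {coefficients.size}"
        )
    X = design_matrix(spec, stack, cells)
    return coefficients[0] + X @ coefficients[1:]


def transition_probability(kappa_values: np.ndarray) -> np.ndarray:
    """Elementwise logistic 1/(1+exp(-kappa)); saturates at 0/1 in floats."""
    return expit(np.asarray(kappa_values, dtype=np.float64))


def log_likelihood(Z: np.ndarray, P: np.ndarray) -> float:
    """Bernoulli log-likelihood sum(log P where Z=1, log(1-P) where Z=0)."""
    Z = np.asarray(Z)
    P = np.asarray(P, dtype=np.float64)
    if Z.shape != P.shape:
        raise ValueError(f"Z and P lengths differ: {Z.shape} vs {P.shape}")
    P = np.clip(P, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(np.sum(np.where(Z == 1, np.log(P), np.log1p(-P))))


def calibration_data(
    start: LandCoverGrid, end: LandCoverGrid, transition: TransitionKind
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome vector for one calibration interval.

    Returns (cells, Z): flat indices of the transition's source-class cells
    at the interval start, and Z=1 where the end map shows the target
    class.  Cells that moved to the third class leave the likelihood (they
    are evidence about a different transition), as do NODATA cells.
    """
    if start.shape != end.shape:
        raise ValueError("calibration maps differ in shape")
    s = start.cells.ravel()
    e = end.cells.ravel()
    keep = (
        (s == transition.source_state)
        & (e != NODATA)
        & (e != transition.third_state)
    )
    cells = np.flatnonzero(keep)
    Z = (e[cells] == transition.target_state).astype(np.int8)
    return cells, Z


# ---------------------------------------------------------------------------
# MCMC


def _bernoulli_ll_from_kappa(sign: np.ndarray, kappa_vals: np.ndarray) -> float:
    # ll = -sum softplus(-sign * kappa), sign = +1 for Z=1, -1 for Z=0
    return -float(np.logaddexp(0.0, -sign * kappa_vals).sum())


def fit_mcmc(
    spec: PredictorSpec,
    Z: np.ndarray,
    stack: CovariateStack,
    cells: np.ndarray,
    chain: ChainConfig | None = None,
) -> CoefficientPosterior:
    """Sample the coefficient posterior by componentwise random-walk Metropolis.

    Covariates are standardised internally (the flat prior box of width
    ``2*prior_bound`` applies on that scale, where it is effectively
    unbounded) and the retained draws are transformed back to the raw
    covariate units for reporting, so distance coefficients come out in
    per-metre units.  Deterministic given ``chain.seed``.
    """
    chain = chain or ChainConfig()
    Z = np.asarray(Z)
    n = Z.size
    k = spec.n_coefficients
    if n < 10 * k:
        raise ValueError(
            f"need >= {10 * k} training cells for {k} coefficients, got {n}"
        )
    X = design_matrix(spec, stack, cells)
    mu = X.mean(axis=0) if X.size else np.empty(0)
    sd = X.std(axis=0) if X.size else np.empty(0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    cols = [np.ones(n)] + [Xs[:, j] for j in range(k - 1)]
    sign = np.where(Z == 1, 1.0, -1.0)

    rng = np.random.default_rng(chain.seed)
    b = np.zeros(k)
    pbar = float(np.clip(Z.mean(), 0.01, 0.99))
    b[0] = np.log(pbar / (1 - pbar))
    kap = cols[0] * b[0]
    ll = _bernoulli_ll_from_kappa(sign, kap)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood at the initial point")

    burn = int(chain.iterations * chain.burn_in)
    thin = max(1, (chain.iterations - burn) // chain.n_retain)
    steps = np.full(k, chain.init_step)
    acc_win = np.zeros(k)
    prop_win = np.zeros(k)
    acc_post = 0
    prop_post = 0
    retained: list[np.ndarray] = []

    for it in range(chain.iterations):
        for j in range(k):
            delta = steps[j] * rng.standard_normal()
            bj_new = b[j] + delta
            prop_win[j] += 1
            if it >= burn:
                prop_post += 1
            if abs(bj_new) > chain.prior_bound:
                continue
            kap_new = kap + delta * cols[j]
            ll_new = _bernoulli_ll_from_kappa(sign, kap_new)
            if np.log(rng.random()) < ll_new - ll:
                b[j] = bj_new
                kap = kap_new
                ll = ll_new
                acc_win[j] += 1
                if it >= burn:
                    acc_post += 1
        if it < burn and (it + 1) % chain.adapt_interval == 0:
            rate = acc_win / np.maximum(prop_win, 1)
            steps[rate > 0.5] *= 1.6
            steps[rate < 0.25] *= 0.7
            np.clip(steps, 1e-6, chain.prior_bound, out=steps)
            acc_win[:] = 0
            prop_win[:] = 0
        if it >= burn and (it - burn) % thin == 0:
            retained.append(b.copy())

    acc_rate = acc_post / max(prop_post, 1)
    if not (0.01 < acc_rate < 0.9):
        warnings.warn(
            f"MCMC acceptance rate {acc_rate:.3f} outside (0.01, 0.9) for "
            f"{spec.transition.label} {spec.covariate_names}",
            RuntimeWarning,
        )

    S = np.asarray(retained)
    # back-transform standardised coefficients to raw covariate units
    raw = S.copy()
    if k > 1:
        raw[:, 1:] = S[:, 1:] / sd
        raw[:, 0] = S[:, 0] - S[:, 1:] @ (mu / sd)
    mean = raw.mean(axis=0)
    ci95 = np.percentile(raw, [2.5, 97.5], axis=0).T
    return CoefficientPosterior(
        names=spec.coefficient_names,
        samples=raw,
        mean=mean,
        ci95=ci95,
        acceptance_rate=acc_rate,
    )


# ---------------------------------------------------------------------------
# Forward stepwise selection


class DegenerateSplitError(ValueError):
    """A 50/50 split left one half without any observed transitions."""


def _score(
    spec: PredictorSpec,
    posterior: CoefficientPosterior,
    stack: CovariateStack,
    cells: np.ndarray,
    Z: np.ndarray,
) -> float:
    P = transition_probability(kappa(spec, posterior.mean, stack, cells))
    return log_likelihood(Z, P)


def forward_stepwise(
    transition: TransitionKind,
    candidates: Sequence[str],
    stack: CovariateStack,
    Z: np.ndarray,
    cells: np.ndarray,
    chain: ChainConfig | None = None,
    split_seed: int = 0,
) -> FitResult:
    """Forward stepwise covariate selection scored by held-out likelihood.

    Source cells are split 50/50 once (seeded; the same split is reused at
    every step so test likelihoods are comparable), models are fitted on
    the training half by MCMC, and an addition is kept only if it strictly
    improves the test-half log-likelihood evaluated at the posterior mean.
    Ties therefore resolve toward fewer covariates, then candidate order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("forward_stepwise needs at least one candidate covariate")
    PredictorSpec(transition, tuple(candidates))  # validate admissibility early

    Z = np.asarray(Z)
    cells = np.asarray(cells)
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(cells.size)
    half = cells.size // 2
    tr, te = perm[:half], perm[half:]
    for name, idx in (("training", tr), ("test", te)):
        if Z[idx].sum() == 0:
            raise DegenerateSplitError(
                f"{transition.label}: {name} half of the 50/50 split has no "
                "observed transitions"
            )
    chain = chain or ChainConfig()

    def fit_and_score(names: tuple[str, ...], fit_seed: int):
        spec = PredictorSpec(transition, names)
        post = fit_mcmc(spec, Z[tr], stack, cells[tr], chain.replace(seed=fit_seed))
        test_ll = _score(spec, post, stack, cells[te], Z[te])
        train_ll = _score(spec, post, stack, cells[tr], Z[tr])
        return spec, post, train_ll, test_ll

    seed_counter = int(chain.seed)
    best = fit_and_score((), seed_counter)
    current: tuple[str, ...] = ()
    remaining = list(candidates)
    while remaining:
        step_best = None
        for cand in remaining:
            seed_counter += 1
            trial = fit_and_score(current + (cand,), seed_counter)
            if step_best is None or trial[3] > step_best[3]:
                step_best = trial
        if step_best is not None and step_best[3] > best[3]:
            best = step_best
            current = best[0].covariate_names
            remaining = [c for c in remaining if c not in current]
        else:
            break

    spec, post, train_ll, test_ll = best
    return FitResult(spec, post, train_ll, test_ll, split_seed=split_seed)


def fit_transition(
    series,
    features,
    start_year: int,
    end_year: int,
    transition: TransitionKind,
    candidates: Sequence[str] | None = None,
    chain: ChainConfig | None = None,
    split_seed: int = 0,
    radius: int = 1,
    static: dict | None = None,
):
    """Convenience: build the stack and calibration data for (start, end),
    then run stepwise selection.  Returns (FitResult, stack)."""
    from .covariates import assemble_stack

    start = series.grid_for(start_year)
    end = series.grid_for(end_year)
    stack = assemble_stack(
        start, series, features, year=start_year, radius=radius, static=static
    )
    cells, Z = calibration_data(start, end, transition)
    if candidates is None:
        candidates = [n for n in transition.candidate_layers()]
    fit = forward_stepwise(
        transition, candidates, stack, Z, cells, chain=chain, split_seed=split_seed
    )
    return fit, stack
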