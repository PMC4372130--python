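# stoclcc

Stochastic, spatially explicit modelling of land-cover change on
categorical raster time series with three states — forest, regeneration
(secondary forest) and deforested — for landscape ecologists studying
deforestation frontiers and forest regrowth.

Three transitions are modelled independently per pixel: forest→deforested
(FtoD), regeneration→deforested (RtoD) and deforested→regeneration
(DtoR).  The probability that a source-class cell *x* makes its
transition over an interval of *n* years is logistic,

    P_x = 1 / (1 + exp(−κ_x)),        κ_x = β₀ + Σ_j β_j c_j(x),

with covariates c_j drawn from distance to roads/rivers/settlements,
protected-area status, neighbourhood *contagion* (the fraction of
neighbours already deforested or regenerating) and, for RtoD, land-use
history metrics (period of active land use, age of regenerating forest,
frequency of clearance).  Coefficients are sampled by random-walk
Metropolis from the Bernoulli likelihood

    ℓ = Σ_x log[ Z_x P_x + (1 − Z_x)(1 − P_x) ],

covariates are chosen by forward stepwise selection against a held-out
50% of cells, and the fitted models drive a stochastic cellular
simulator: per step, every source cell flips by an independent uniform
draw against its probability, dynamic covariates are recomputed, and the
whole run is repeated (default 100 iterations) with joint posterior
coefficient draws to produce prediction envelopes.  Predictions are
scored by *perfect match*: the percentage of observed changed cells whose
exact transition is predicted at the exact location.  On top of the
pipeline sit two meta-analyses — a calibration-window experiment
(enumerate every pair of map dates whose prediction sequence lands on a
target year, run each, decompose the scores by sequential ANOVA) and
temporal trend tests on univariate parameter series.  A synthetic
landscape generator with known ground-truth coefficients makes the whole
chain testable end to end.

See `docs/methods.md` for the full model description and conventions.

## Worked example

```python
import numpy as np
from stoclcc import (
    SyntheticScenario, generate_truth_series, TransitionKind,
    ChainConfig, fit_transition, SimulationConfig, simulate,
    change_code, perfect_match, enumerate_designs,
)

# a 80x80 synthetic landscape observed in 1986, 2000, 2001 and 2005
scenario = SyntheticScenario(shape=(80, 80), seed=1,
                             years=(1986, 2000, 2001, 2005))
series = generate_truth_series(scenario)

# stepwise-fit the forest->deforested transition on the 2000-2001 pair
fit, _ = fit_transition(
    series, scenario.features, 2000, 2001, TransitionKind.FtoD,
    candidates=["contagion_defor", "dist_roads", "protected"],
    chain=ChainConfig(iterations=2000, n_retain=400, seed=1),
)
print(fit.spec.covariate_names)
print(np.round(fit.posterior.mean, 4))

# simulate 5 annual steps from 2000 and validate against the 2005 map
out = simulate(series.grid_for(2000),
               {TransitionKind.FtoD: fit, TransitionKind.RtoD: None,
                TransitionKind.DtoR: None},
               scenario.features, series.upto(2001),
               SimulationConfig(n_iterations=100, n_steps=5, seed=1))
observed = change_code(series.grid_for(2000), series.grid_for(2005))
predicted = [change_code(series.grid_for(2000), m) for m in out.maps_for_year(2005)]
print(round(perfect_match(observed, predicted).mean, 1))
```

prints

```
('contagion_defor', 'protected', 'dist_roads')
[-3.7232e+00  4.0047e+00 -1.4077e+00 -2.0000e-04]
19.1
```

— the covariates in selection order; the posterior-mean coefficients
(intercept, contagion, protection, per-metre road distance), close to the
generating truth (−3.5, 4.0, −1.5, −0.00056); and the mean perfect match
(%): about a fifth of the cells observed to change 2000→2005 — with only
the deforestation transition modelled here — were predicted with the
right transition at the right location, averaged over 100 stochastic
iterations.

The same pipeline is scriptable from a shell (`stoclcc synth | fit |
simulate | validate | designs | trends | anova`); try

```bash
stoclcc designs --years 1991,1995,1996,1997,2001 --target 2011
```

which lists every calibration pair whose prediction sequence lands on
2011 — e.g. the 1991–1995 design (transition length 4) reaches it as its
5th time step, while 1991–1997 never does.

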