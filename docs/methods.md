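# Methods

## The model

`stoclcc` models change among three land-cover states on a raster
landscape — deforested (0), forest (1) and regeneration (2) — as three
independent per-pixel transitions: forest→deforested (FtoD),
regeneration→deforested (RtoD) and deforested→regeneration (DtoR).
For a source-class cell *x* the probability of making its transition over
one time interval of *n* years is logistic,

    P_x = 1 / (1 + exp(-kappa_x)),
    kappa_x = b0 + sum_j b_j * c_j(x),

where the covariates `c_j` are of two kinds:

* **static** — Euclidean distance (metres) from the cell centre to the
  nearest road, river and settlement cell, and a 0/1 protected-area
  indicator; computed once per landscape;
* **dynamic** — recomputed from the current map at every step: the
  *contagion* proportions (fraction of neighbouring cells already
  deforested, or in regeneration), and for RtoD three land-use history
  metrics: PALU (calendar years the cell spent deforested before its most
  recent abandonment), ARF (years since that abandonment) and FC (number
  of observed clearance events so far).

Contagion makes change beget change: a cell whose neighbours were cleared
recently carries a higher clearing probability at the next step, which is
what produces spatially clustered, self-accelerating frontiers.

The likelihood of a model over the source cells of one calibration
interval (t, t+n) is the Bernoulli sum

    ll = sum_x log[ Z_x P_x + (1 - Z_x)(1 - P_x) ],

with Z_x = 1 when the cell shows the target class at t+n.  Source cells
that moved to the *third* class over the interval are excluded from that
transition's likelihood — they are evidence about a different transition.
NODATA cells (the shared water mask, the union of all per-date masks) are
excluded from everything.

## Fitting

Coefficients are sampled by componentwise Gaussian random-walk Metropolis
under independent flat priors on [-50, 50] per coefficient.  Covariates
are standardised internally (so the prior box is effectively unbounded and
the sampler is well conditioned) and retained draws are back-transformed
to raw units, so distance coefficients are reported per metre.  Chain
defaults: 20,000 sweeps, first half discarded as burn-in, thinned to
~1,000 retained draws; per-coefficient step sizes adapt toward a
moderate acceptance rate during burn-in only, so the retained chain is a
valid (fixed-kernel) Metropolis sample.  The chain is initialised at the
intercept-only MLE with zero slopes.  Probabilities are clamped to
[1e-12, 1-1e-12] inside the likelihood.  An acceptance rate outside
(0.01, 0.9) after adaptation triggers a warning.  Everything is
deterministic given the chain seed.

Covariate selection is forward stepwise, scored by held-out likelihood:
the source cells are split 50/50 once per run (seeded; the same split is
reused at every step so test likelihoods are comparable between steps),
candidate additions are fitted on the training half and scored on the
test half at the posterior-mean coefficients, and an addition is kept
only when it strictly improves the test log-likelihood — so ties resolve
toward fewer covariates, then candidate order.  A split that leaves
either half with no observed transitions raises an error naming the
transition.  PALU/ARF/FC are admissible candidates for RtoD only.

## Simulation

A simulation advances the landscape in steps of one transition interval.
Within a step all three transitions are applied *synchronously*: the
dynamic covariates and all three probability surfaces are computed from
the incoming map, then every source cell flips independently by a uniform
draw.  Between steps the dynamic covariates are recomputed from the
simulated trajectory (history metrics use the same
last-observation-carried-forward convention as calibration).  Each of the
`n_iterations` (default 100) repetitions draws one *joint* row of the
posterior sample per transition — joint rows preserve the posterior
correlation between, e.g., intercept and contagion, which independent
per-coefficient draws would destroy — and owns an RNG stream derived from
(seed, iteration), so iterations are independently reproducible.  Outputs
are the per-iteration predicted maps, per-step mean probability surfaces
and per-step event counts, from which prediction envelopes carrying the
parameter uncertainty are read off directly.

## Validation

A map pair is reduced to change codes over the three modelled transitions
(1 = FtoD, 2 = RtoD, 3 = DtoR, 0 otherwise).  *Perfect match* is the
percentage of observed changed cells whose exact code is predicted at the
exact location, averaged over iterations.  Only observed change enters
the denominator: unchanged cells are never validated, and predicted
change at locations with no observed change is not penalised.  The second
property is a real asymmetry of the metric (false-positive change is
free); it is reproduced deliberately, not patched, and should be kept in
mind when comparing models with very different predicted change totals.

## Calibration-window experiments

A model design is a calibration pair (start, end) with transition length
n = end - start.  The design steps forward from the **start-year map**, so
its first prediction (time step 1) is the calibration end year itself, and
it reaches a target year exactly when (target - start) is a multiple of n
— a 1991–1995 design reaches 2011 as its 5th step, 1991–1996 as its 4th,
1991–2001 as its 2nd, while 1991–1997 (predicting 1997, 2003, 2009, …)
never does.  Validation years are the predicted years after the end year
for which a map exists; observed and predicted change are both coded
against the start-year map.

The perfect-match results table is decomposed by a sequential (Type I)
ANOVA with initial year, transition length, time step and validation year
as *numeric* covariates (1 df per term) in a fixed term order: the four
main effects, five two-way interactions, four three-way interactions and
the four-way interaction.  The transition-length × time-step product is
excluded: by the design arithmetic, step·length = validation − initial −
length exactly, so that column is a linear combination of terms already
in the model.  Factors are centred before products are formed —
calendar-year-scale raw products are numerically degenerate in double
precision — and each term's SS is the drop in residual SS when its column
enters, so term SS plus residual SS reproduce the total SS identically.

Univariate parameter series refit each single-covariate model on every
adjacent pair of map dates; temporal trends in the posterior means (and
in landscape composition and transition rates) are tested by ordinary
least squares with df = n − 2, using the interval end year as the time
coordinate.  The annualised transition rate of an interval is defined as
events / source-class cells at the interval start / interval length in
years.

## The synthetic-landscape generator

The generator exists so that every stage — covariates, fitting,
selection, simulation, validation, the design grid — can be exercised
against a known truth.  It builds parametric driver geometry (two road
polylines crossing the grid, one river, one settlement on a road, one
rectangular protected area covering 20–30% of the landscape, and a water
blob of ~2% of cells applied as the shared NODATA mask), then simulates
land cover forward **annually** from known coefficients through the exact
machinery used for fitting, recording grids only at the requested
observation years.  The default calendar is 20 dates over 1986–2011 with
gaps, the cadence of a Landsat-derived archive.  Default truth
coefficients follow the field's reporting conventions for 30 m
landscapes — contagion terms of order 1 (FtoD strongest at 4.0),
distance-to-road terms of order 1e-4 per metre (negative for both
deforestation transitions, positive for regeneration), protection terms
of order 1 (strongly negative for FtoD) — with intercepts chosen so the
landscape loses forest at a few percent per year near drivers, a
realistic frontier dynamic.  Coefficients may be given as {year: value}
breakpoints (piecewise-linear) to inject temporal drift.

Because generation is annual, a fitted model matches the generative
process exactly only for one-year calibration intervals; recovery and
coverage tests therefore calibrate on adjacent-year pairs.  The generator
does **not** emulate satellite classification error, road-network growth,
georeferencing, or any demand-side constraint on change rates — so
passing tests demonstrate that the estimation and simulation machinery is
correct and calibrated *under the model's own assumptions*, not that the
model is adequate for any particular real landscape.

## Problem sizes and numerical choices in the test suite

The statistical tests run at desk scale, chosen as the smallest sizes at
which the checks are statistically meaningful: 70–100 grids
(≈5,000–10,000 cells), chains of 1,200–6,000 sweeps retaining 300–600
draws, simulations of 15–100 iterations, and 5–20 seeded replicates per
check.  Library defaults remain at the full settings (20,000-sweep
chains, 100-iteration simulations).  Credible-interval coverage is
assessed as the pooled fraction of (coefficient, seed) pairs whose true
value falls in the 95% interval, per transition, with a 0.90 pass line;
a joint all-coefficients-per-seed criterion would fail even for a
perfectly calibrated sampler (0.95^k < 0.90 for k ≥ 2).

Other numerical conventions: states between observation dates are
piecewise-constant (last observation carried forward) and a transition is
attributed to the later date of the bracketing pair; contagion uses the
square Moore neighbourhood of half-width 1 (8 neighbours), centre
excluded, normalised by the count of valid in-bounds neighbours (edge and
coast cells use their actual neighbour count); the neighbourhood radius
is configurable.  A covariate with zero variance in the training data is
left unstandardised rather than rejected; stepwise selection will not
retain it.

## Known limitations

* Raster I/O covers ESRI ASCII grids and plain single-band TIFF; no
  geo-referencing beyond cell size is carried, and vector inputs must be
  pre-rasterised to boolean masks.
* The perfect-match metric's blindness to false-positive change (above).
* The simulator has no demand/quota layer: aggregate change rates emerge
  bottom-up from the per-cell probabilities.
* Univariate parameter series require at least three map dates (two
  intervals); the trend test additionally needs three points, i.e. four
  dates.
* The MCMC sampler is single-chain; convergence is monitored only through
  the acceptance-rate warning and the seeded recovery tests, which is
  adequate for the well-conditioned standardised logistic posteriors used
  here but would need supplementing (multiple chains, R-hat) for harder
  posteriors.
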