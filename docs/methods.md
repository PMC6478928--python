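# Methods

## The single-pool bomb-radiocarbon model

The model treats the 0–20 cm mineral-soil organic carbon stock as one
homogeneous reservoir at steady state: inputs equal outputs, and every
carbon atom is equally likely to leave, at the first-order decomposition
rate k (yr⁻¹).  Working in absolute fraction modern F (Δ¹⁴C/1000 + 1),
the pool's radiocarbon balance is

    dF/dt = k·F_atm(t) − (k + λ)·F

— input of contemporary atmospheric carbon, loss by decomposition and by
radioactive decay (λ = 1/8267 yr⁻¹, the inverse Godwin mean life).  The
implementation steps this with the explicit monthly recursion

    F(t+h) = k·h·F_atm(t+h) + F(t)·(1 − h·(k + λ)),   h = 1/12 yr.

Assumptions worth keeping in mind:

- **Steady state and spin-up.**  The pool is initialised at the analytic
  steady state F₀ = k·F̄_atm/(k+λ) against the mean forcing of the 30
  years before 1950, then run transiently from 1950 through the sampling
  year.  Soils gaining or losing stock violate this.
- **No lag times.**  Carbon enters the pool the moment it is fixed;
  litter residence above the mineral soil is ignored.  This biases τ
  slightly low for slow pools.
- **One pool.**  Real SOC is a continuum of cycling rates.  The two
  metrics the package computes, τ₁₄C and τᵢ, bracket that continuum (see
  below) but neither resolves it; multi-pool models are out of scope.

### Numerical choices

- **Forcing sampling.**  Published atmospheric Δ¹⁴C compilations report
  monthly (or coarser) *mean* values.  The recursion therefore takes
  F_atm for the step ending at t+h as the month's mean of the linearly
  interpolated curve — the segment midpoint, exact for a piecewise-linear
  record.  Right-endpoint sampling would add an O(h) half-step bias of
  ~0.6‰ at τ = 10 yr; with month-mean sampling the recursion stays within
  0.37‰ of a high-accuracy integration of the continuous model for
  τ ∈ [10, 1000] yr (the test suite checks 0.5‰).
- **Interpolation is linear, not spline** — splines overshoot near the
  1964 bomb peak.  Past the record's end the last segment is extended
  linearly with a warning (sampling year 2014 exceeds common
  compilations), floored at −1000‰.  Years before the record start are an
  error: spin-up must begin inside the record.
- **Δ-literal variant.**  A recursion applied verbatim to Δ¹⁴C values
  (config `space="delta_literal"`) differs from the fraction-modern form
  by the −1000·h·λ decay-offset term — a few ‰ at centennial τ.  The
  fraction-modern form is the default because it is the discretisation of
  the physical balance; the literal form is retained for comparability.
- **Euler stability** requires h·(k+λ) < 1, i.e. τ longer than about one
  month; shorter τ raises an error advising a smaller h.

### Inversion and its two branches

`invert_tau` scans g(τ) = model(1/τ) − Δ_obs on a ≥200-point log grid
over τ ∈ [1, 50 000] yr, brackets every sign change and refines each by
Brent bisection to 10⁻⁶ relative.  Because atmospheric Δ¹⁴C rose to the
1964 peak and has declined since, modelled Δ¹⁴C(τ) at a 2014 sampling
date rises to a maximum (at τ ≈ 34 yr under the bundled synthetic curve)
and then falls: bomb-enriched observations admit a fast and a slow
solution.  Following the convention for mineral subsoils, the *larger* τ
(post-bomb-peak branch) is always returned; the solution object records
how many roots were found and which branch was taken.  An observation
within 0.001‰ of the model's maximum is accepted as the tangent double
root.  Observations outside the attainable range raise an error that
reports that range.  The ±1σ interval re-inverts at Δ_obs ± σ on the
same branch; if one side is un-invertible the interval is half-open with
a warning.

Consequence of the branch rule: forward–inverse round-trips recover τ
exactly on the slow branch, but a true τ below the branch point maps to
its conjugate slow root *by design*.  The tests assert 0.5% recovery on
the slow branch and exact-observation reproduction below it.

## Radiocarbon algebra

Δ¹⁴C ↔ fraction modern conversion is the absolute (sampling-year)
convention F = Δ/1000 + 1.  Standards decay-correct from 1950 by
e^(−λ·(y−1950)).  Blank correction assumes a constant contaminant mass
m_c of fraction modern F_c in every sample and inverts the mixing
balance F_s = (F_m·m_m − F_c·m_c)/(m_m − m_c); its 1σ is propagated
first-order over F_m, F_c and m_c (the sample mass is treated as exact —
weighing error is negligible next to the others).  Tests verify the
propagated σ against 10⁴-draw Monte Carlo to 10%.  δ¹³C fractionation
normalisation is assumed already applied by the AMS facility.

## Incubation turnover and DOC

CO₂ respired between trap changes (days 4, 13, 30, 63, 92, 121, 150,
181) is quantified from the conductivity drop of 20 ml 1 M NaOH traps
through a linear calibration.  Stoichiometry (CO₂ + 2 NaOH → Na₂CO₃)
caps a trap at 0.1201 g C; any interval reaching ≥80% of capacity flags
the series — conductivity response is no longer linear there, and such
series get no τᵢ.  Slightly negative conductivity-derived masses (noise)
clamp to zero with a warning; strongly negative ones are errors.

Fluxes are normalised to the sample's initial organic carbon
(TOC · dry mass), making τᵢ independent of the mass incubated.  τᵢ is
the stock/flux ratio: cumulative 181-day CO₂-C per kg OC, scaled by
365.25/181, divided into the 1000 g stock.  The linear annualisation (no
decay-curve fit) carries a known bias for a truly exponential flux,
τ̂ = d/(1−e^(−kd)) with d = 0.496 yr: +2.5% at τ = 10 yr, +5% at τ = 5
yr, <1% at τ = 29 yr.  DOC leached at days 4, 13, 30, 63, 121, 181 is
summed per kg OC; it is ~1% of total losses, so whether it joins the τᵢ
denominator (config switch, default off) is near-immaterial.  Replicates
are averaged at the flux level before the ratio.  Pre-incubation
emissions are not part of the series.

## Site-selection design

The design module exists because environmental drivers covary across
natural gradients (colder sites are moister; wetter sites are more
acidic), which makes their regression effects inseparable in random
samples.  The procedure: (1) drop candidate sites with slope > 50%
(erosion would violate steady state), long-term monitoring sites exempt;
(2) median-split the filtered population on temperature (TT−/TT+) and on
the dryness index — the count of months with precipitation below Penman
potential evapotranspiration (MI− = dry, MI+ = moist; PET is an input,
never computed here); ties go to the lower covariate bin; (3) reduce pH,
clay, slope and N/E/S/W orientation to two axes by principal coordinates
analysis of a Gower distance matrix (range-scaled numerics + simple
matching for orientation); (4) stratify by region × climate category,
allocate the target size proportionally (largest remainder, capped at
cell size with redistribution), and fill each cell by greedy
farthest-point sampling in the PCo1–PCo2 plane, anchored at the site
farthest from the origin, ties broken by site id.

Gradient studies of this kind often select sites partly by hand; the
greedy criterion is a reproducible alternative, and the returned
`orthogonality_report` (max |pairwise correlation| among TT, MI, PCo1,
PCo2 and region dummies; dummy–dummy pairs within the region block are
excluded as structurally negative) measures design quality instead of
claiming to replicate manual choices.  Plane-spread farthest-point
sampling was chosen over spreading the scalar radius after the latter
proved to *induce* PCo1–PCo2 correlation in the selected set.

PCoA coordinates come from scikit-bio; the signed eigenvalue spectrum is
recomputed from the double-centred −½D² matrix because negative
eigenvalues (possible for Gower) are themselves informative and
scikit-bio zeroes them.  A perfectly one-dimensional configuration
yields a second axis of zeros rather than an error.  For regression (as
opposed to selection), orientation is encoded as (sin θ, cos θ) of the
aspect angle — one two-degree-of-freedom term.

## Sequential ANOVA and order screening

Sums of squares are Type I (sequential) exclusively: each term's SS is
the residual-SS drop when it is added after all preceding terms, its df
the design-matrix rank increase; F compares the term mean square to the
full-model residual mean square.  The implementation builds term-grouped
design matrices (treatment contrasts, first sorted level as reference)
and computes nested least-squares fits directly; statsmodels'
`anova_lm(typ=1)` serves as an independent cross-check in the tests.
Type-I SS is order-dependent unless the design is orthogonal — which is
exactly why the order-permutation screen works: the region block and the
climate interaction model are refitted with main effects swapped (and,
for single drivers, with the driver first, second, or last), and a
driver counts as significant only if p < 0.05 in *every* ordering.
Order-dependent significance is reported as "crossed out" — an artefact
of residual collinearity, not evidence.  Screening can only remove false
positives, never add them.

Turnover responses are natural-log transformed (results are invariant to
the base); DOC and drivers enter untransformed.  Significance codes are
the conventional ***/**/*/· at 0.001/0.01/0.05/0.1; the · code is
reported but never drives verdicts.  No multiple-testing correction is
applied.  Non-finite responses are dropped case-wise.  Default
exclusions mirror the study design the package emulates: sites 6 and 24
(trap saturation) and 12 (residual diagnostics) for τᵢ, site 40
(implausible τ from over-deep sampling) for τ₁₄C, saturated sites for
DOC.

## The synthetic-study generator

`synthdata` emulates the structure of a regional gradient study so the
pipeline can be validated end-to-end against known truth.  What it
reproduces:

- a 709-entry working population with Gaussian-copula drivers —
  temperature N(7, 2.5) °C, a gamma-quantile dryness count, pH N(5, 0.9)
  clipped to [3.2, 7.8], lognormal clay (~18%), right-skewed slope
  truncated at 50% for non-monitoring sites — with population Pearson
  targets r(pH, clay) = 0.39, r(pH, dryness) = +0.35 (wetter ↔ more
  acid) and a nuisance r(temp, dryness) = +0.30 for the selection to
  remove.  Latent correlations are divided by first-order Hermite
  attenuation coefficients (NORTA matching) so the *output* correlations
  hit the targets; clay clipping affects <1% of rows;
- five regions whose odds tilt with temperature, with warm-moist Alpine
  candidates reassigned so that combination is structurally missing, as
  in real stratified networks;
- true responses from a planted linear effect structure on standardised
  drivers (pH shortens both turnover times; dryness shortens only τᵢ;
  clay and slope suppress DOC; temperature does nothing), plus Gaussian
  score noise, affinely mapped into the published ranges — log τ₁₄C into
  [67, 511] yr, log τᵢ into [5, 29] yr, DOC into [0.15, 0.85] g kg⁻¹ OC
  (~1–2% of total losses).  The mapping is anchored on the QC-retained
  sites because the published ranges describe the retained sets;
- observations: Δ¹⁴C from the forward model plus σ = 3‰ AMS noise;
  trap-interval CO₂ from first-order decay at 1/τᵢ with 5% multiplicative
  noise, 3 replicates; DOC split over the leach days; TOC lognormal
  around 50 g kg⁻¹, 40 g dry mass;
- planted pathologies exercising every QC path: overfilled traps at
  sites 6 and 24, and a τ₁₄C outlier (1140 yr) at site 40.

What it does *not* emulate — and hence what passing tests do not show
about real data: spatial autocorrelation, non-steady-state stocks,
pyrogenic carbon, depth structure, multi-pool kinetics, real atmospheric
curve shape (the bundled curve is a clean ramp-plus-exponential), or
measured-driver error.  Parameter recovery here demonstrates that the
*pipeline* is correct, not that the one-pool model is adequate for any
particular soil.

All randomness flows through one seeded `numpy.random.Generator`; a
fixed seed reproduces every table byte-identically.

## Problem sizes and runtime

Default test and acceptance sizes: 709-site populations, 54-site
studies, 50 replicate studies for the pattern-recovery rate, 1000 null
simulations for ANOVA calibration, 10⁴ Monte-Carlo draws for the blank
σ check.  The full suite runs in under two minutes on one CPU; the
acceptance script in about one.

## Known limitations

- The τᵢ estimator's linear annualisation biases fast pools high (5% at
  τ = 5 yr); a decay-curve fit would remove this at the cost of a model
  assumption the stock/flux definition avoids.
- The inversion's branch convention makes sub-branch-point turnover
  times unidentifiable from a single Δ¹⁴C value — an intrinsic property
  of bomb-spike dating, not of the solver.
- The greedy selection optimises spread, not the correlation report
  directly; a population with strong climate–region association can
  still leave residual correlation in the selected set (it is reported,
  not hidden).
- With an empty DOC column the DOC analyses degrade to zeros rather
  than being skipped.
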