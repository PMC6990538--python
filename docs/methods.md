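# Methods

## Data model and design

The unit of analysis is the stratum: one sex × age (whole years) ×
examination year cell of a school-health registry, summarised by its
count `n` and mean outcome (systolic/diastolic BP in mmHg, BMI in
kg/m²). An `APCDesign` is a rectangle of consecutive integer ages
(`A` levels) by consecutive examination years (`P` levels); each cell
belongs to birth cohort `k = period − age`, giving `C = A + P − 1`
cohort indices along the anti-diagonals. The surveillance designs the
package is shaped around are 10 ages (9–18) × 16 years (1999–2014) for
BP — 160 strata, 51 effect parameters, 25 cohorts — and 13 ages (6–18)
× 19 years (1996–2014) for BMI — 247 strata, 63 parameters, 31 cohorts.

Because a child of age `a` examined in school year `p` can have been
born in either of two adjacent calendar years, cohorts are displayed
with two-year labels `"(k−1)–k"`; the label convention is anchored on
the published figure captions (earliest label `1980–1981` for age 18 in
1999, latest observed `2004–2005` for age 9 in 2014, central cohort
`1992–1993`). A variant phrasing in the source's running text ("born
in 2004 or 2005 … categorized as 2004–2005" for age 10 in 2014/5) is
inconsistent with those anchors and is not followed. Similarly the
phrase "cohorts born from 1980 to 2005" counts the 26 calendar years
touched by the 25 overlapping two-year labels, not 26 cohorts.

Per-stratum averages in design summaries truncate toward zero
(196,299 boys over 160 strata → 1226), matching the published
bookkeeping.

## The APC regression

Stratum means are modelled as `ȳ ~ Normal(α_a + π_p + γ_{p−a}, σ²/w)`.
The default is `w = 1` — the analysis models the cell means directly,
which is appropriate when every stratum is large (10²–10³ children) and
keeps σ interpretable as the cell-level residual SD; `weighting="n"`
is available when stratum sizes vary enough to matter. Sexes are
always fitted separately; there are no shared parameters.

**Identification.** `cohort = period − age` makes the three linear
trends jointly unidentified (the unconstrained indicator model has a
3-dimensional null space: two level shifts and one trend rotation).
The package pins the second and penultimate period effects and the
central cohort effect (position ⌈C/2⌉) to zero, leaving the age effects
unconstrained to carry the absolute level. Sub-models drop whole
effect blocks together with the constraints they no longer need: AP
keeps only the second-period constraint, AC only the central cohort,
A none — in each case exactly the null-space dimension. The design
matrix is checked for full column rank and a rank-deficiency error
names the deficit. Fitted cell means `α + π + γ` are invariant to the
particular constraint choice (verified by refitting under alternative
corner constraints); individual effect values are **not**, which is why
only second-order features of the effect curves are interpreted.

**Priors.** Each effect vector has an RW2 prior: flat on its first two
elements, `θ_j ~ N(2θ_{j−1} − θ_{j−2}, τ²)` forward from there, i.e. a
Gaussian penalty `‖Δ²θ‖²/τ²` whose null space is exactly the affine
functions — the prior smooths curvature and is agnostic about the
(unidentified) trends. σ and the three innovation SDs τ have
uniform(0, U) priors with U = 100 outcome units by default: effectively
flat over every plausible value for mmHg/BMI-scale outcomes while
keeping the posterior proper. The named prior family fixes the form
but not the hyperparameters; U is configurable.

**Sampling.** The effect coefficient vector is conditionally Gaussian
and is drawn jointly (one Cholesky per iteration). σ and each τ are
updated by stepping-out/shrinkage slice sampling on their *collapsed*
conditionals, with the effect vector integrated out analytically — a
partially collapsed Gibbs scheme (order: each τ given the others and σ,
then σ, then a joint effect redraw; the marginalised block is redrawn
downstream of every collapsed update, which keeps the scheme valid).
Collapsing matters: conditioning τ on the current effects creates the
usual funnel when a block's true signal is weak, and the centered
scheme showed R-hat up to ≈1.3 on null-signal fits where the collapsed
scheme sits below 1.05 within a few hundred iterations.

Chains (5 by default) start from the penalized-fit posterior mode plus
chain-indexed Gaussian jitter. The first half of each chain is burn-in.
Convergence is monitored by split-chain R-hat over all free scalar
parameters (rank-normalization available but off by default); if the
maximum exceeds 1.05 the run is repeated with doubled iterations, up to
two doublings, then flagged with a warning — never silently. All
randomness flows from a single integer seed; identical seeds give
byte-identical draws. Degenerate R-hat cases are defined: identical
constant chains → 1; separated constant chains → ∞ with a warning.

**Point-estimate oracle.** `penalized_fit` returns the exact Gaussian
posterior mode at fixed hyperparameters (a generalized ridge solve with
the RW2 penalty). With hyperparameters fixed, the sampler's effect
draws are iid from the exact posterior, so the Gibbs mean must match
the closed form within `sd/√n` Monte-Carlo error; this equivalence is
asserted in the tests. `τ → ∞` removes the penalty (pure least
squares); `τ → 0` collapses a block onto its best linear fit through
the zero references.

**DIC.** `D(θ) = −2 log` normal likelihood of the cell means;
`Dbar` is the posterior mean deviance, `pD = Dbar − D(θ̄)` with θ̄ the
posterior mean of all parameters (plug-in), `DIC = Dbar + pD`. A
caveat documented here deliberately: for adaptive-shrinkage posteriors
the plug-in fit chases noise roughly twice as hard as `pD` measures
(we observe `ΔD(θ̄) ≈ −2·ΔpD` between nested models on null data), so
DIC retains its known mild anti-parsimony bias — when a smaller model
generates the data, the full APC model still wins a nontrivial minority
(~15–20%) of replicates at surveillance-sized strata. Decisive signal
(e.g. a real period effect) produces decisive DIC gaps.

## Projection

For each retained draw, `H` further period and cohort effects are
simulated recursively from the RW2 predictive
`θ_{J+h} = 2θ_{J+h−1} − θ_{J+h−2} + N(0, τ²)` using that draw's own τ,
forward only; age effects are unchanged, and no refitting occurs — the
projection summarises the same posterior as the fit. With τ = 0 the
extension is the exact linear continuation of the last two effects
(asserted to machine precision). Projected cell means are
`α_a + π_p + γ_{p−a}`; projecting an *observed* period reproduces the
fitted values exactly. A 10-year horizon on the BP design (2015–2024)
needs cohorts up to `2024 − 9 = 2015`, i.e. exactly the 10th cohort
extension. Yearly series average cell means over ages per draw —
equal weights by default, since the population age weighting of the
original yearly plots is unstated; any weight vector is accepted, and
the observed portion of a trend plot can show either the fitted or the
raw yearly means (both offered, the choice being likewise unstated).
Credible-interval width is non-decreasing in the forecast step for
pure-RW2 extensions.

## Changepoints

Curvature is the second difference `Δ²θ_j = θ_{j+1} − 2θ_j + θ_{j−1}`,
computed per draw and summarised with credible intervals; it is exactly
invariant under adding any affine function of the index — the property
that makes inflection points constraint-free. An inflection is flagged
where the curvature CrI (95% by default) excludes zero and the absolute
posterior mean exceeds a configurable magnitude floor (default 0; the
original analyses identified inflections visually, so the flagging rule
is this package's own formalisation).

Joinpoint regression fits a continuous piecewise-linear trend with
breakpoints at observed years, exhaustively over placements with at
least two observations strictly on each side of every knot and strictly
between consecutive knots, selecting `k` and placement by
`MBIC(k) = n·ln(SSE_k/n) + (2k+2)·ln(n)`, ties toward fewer joinpoints
then earliest placement. Exact fits are handled by flooring SSE at a
machine-scale epsilon relative to the series' magnitude, so an exactly
linear series ties at every `k` and the tie-break selects zero
joinpoints. This is a deliberately simplified criterion: the NCI
software's permutation test and exact modified-BIC variant are out of
scope. A consequence worth knowing: a BIC-type `(2k+2)ln n` penalty is
only marginally stronger than the noise gain from maximising over knot
placements, so on pure-noise series of 16–19 points the zero-joinpoint
rate is about 0.75–0.9 depending on the noise realisation — adequate
for locating strong slope changes, not a calibrated test.

## Synthetic data generator

The generator emulates the registry's structure: each child has a birth
year; annual visits advance age and period together along the cohort
diagonal from a random entry age; outcomes are independent normal draws
around the additive cell mean `age + period + cohort + N(0, sd)`.
One-record-per-child sampling (uniform over a child's visits, seeded)
mirrors the step the registry analysis uses to remove within-child
correlation. Default truth curves are piecewise linear with the
qualitative features of the real series — age inflection near 10 y
(boys) / 9 y (girls), a period minimum near 2005, cohort inflections
near 1993 and 1998, residual SD 8 mmHg — configurable and with no
claim of quantitative fidelity. What the generator does **not**
emulate: within-child outcome correlation across visits (unstated in
the source; repeat visits are independent draws, which makes
one-per-child sampling a no-op statistically rather than a correction),
measurement-protocol artifacts (re-check rules, cuff sizes), and
year-to-year participation variation. Passing tests therefore
demonstrate correctness of the machinery on additive-truth data, not
robustness to those real-data features. Two-year cohort labelling is a
display concern handled at tabulation; generation uses the exact
integer birth year `period − age`.

The replicate validation studies simulate at the stratum level
directly — a mean of `n` iid `N(µ, sd²)` outcomes is exactly
`N(µ, sd²/n)` — while the record-level path is exercised separately
against the noise-free oracle (`residual_sd = 0` aggregation equals
`truth_to_cell_means` exactly).

## Study sizes and numerical choices

Validation studies are sized for a single CPU: oracle equivalence and
CrI coverage on a 5-age × 6-period grid (200 children/cell, SD 5;
coverage pooled over 200 replicates at 500 iterations × 2 chains); DIC
selection on the full 160-stratum design (1226/cell, SD 8 mmHg, 20
replicates, 1000 iterations — full size because DIC's discrimination
grows with the cells-per-parameter ratio); joinpoint noise behaviour at
50 replicates of 16-year series. Slice samplers bound SDs to
(10⁻⁸, U); Cholesky factorisations fall back to a trace-scaled ridge of
10⁻¹⁰ on numerically borderline systems; cells with fewer than a
configurable floor of records (default 1) are dropped with a warning.

## Known limitations

- Effect values are reference-dependent by construction; anything
  downstream that reads individual `π` or `γ` levels (rather than
  curvature or cell means) inherits the constraint choice.
- DIC's mild anti-parsimony bias and the joinpoint false-positive rate,
  both quantified above.
- Projections are pure RW2 continuations: no scenario shocks, policy
  effects, or covariates.
- The generator's independence assumptions mean within-child
  correlation, if strong in real registries, is untested here.
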