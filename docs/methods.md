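# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
study generator does and does not emulate.

## The piecewise multi-level path model

A path model is a DAG whose nodes carry a response family (gaussian,
binomial-logit, ordinal-treated-as-numeric, or categorical-exogenous) and
a random-intercept nesting (outermost level first, e.g. `nest/individual`
for repeated captures of juveniles within natal nests). Edges are
linear, quadratic (linear + squared term entered together), or
residualized two-way interactions.

**Basis set.** Model fit is tested through the minimum basis set built
with the union-of-parents rule: one claim per non-adjacent unordered
pair, conditioning on the union of both members' parents. This is the
only construction consistent with combining K claims against χ² on
exactly 2K df. Quadratic and interaction edges count as adjacency.
Pairs of exogenous variables are claims too, unless listed under
`free_covariance`; the shipped sparrow model frees the fat–TBW pair
because the fat index is *constructed* orthogonal to TBW (its
independence claim is uninformative by construction and, left in, drags
the combined statistic conservative — measured rejection 0.000 under the
null for that claim alone).

**Claim direction.** The claim's response is the later member in a
deterministic topological order whose ties are broken by nesting depth
and then name, so responses land at the level where the repeated
measurements live. One data-driven refinement: if the declared response
is constant within its innermost grouping while the tested predictor
varies inside those groups (e.g. adult tarsus, one value per individual,
tested against capture date), the regression is turned around. Fitting a
group-constant response on replicated rows is REML-degenerate — the
profile likelihood diverges to the variance-ratio boundary and the
standard errors are roughly halved relative to the correct group-level
regression — while the independence test itself is direction-symmetric.

**Fisher's C.** C = −2 Σ ln pᵢ, compared to χ²(2K); p-values enter
two-sided. Categorical predictors with more than two levels are tested
by a likelihood-ratio comparison of ML fits. A p-value that underflows
is floored at 1e-300 with a warning so C stays finite.

## Mixed-model engine

Gaussian equations are fitted by REML with the fixed effects and residual
variance profiled out; only the log variance ratios ζ_l = log(σ_l/σ_e)
are optimized (L-BFGS-B, bounds ζ ∈ [−8, 4], convergence tolerance 1e-8,
maximum 200 iterations, a second start near zero variance if the first
solve fails or parks at the boundary). All linear algebra runs in the
q-dimensional random-effect space via the Woodbury identity, so the cost
per fit is O(q³) per likelihood evaluation, independent of row count.
The implementation agrees with statsmodels `MixedLM` to ~1e-9 in
log-likelihood and with the classical ANOVA closed forms in balanced
designs; both are kept as independent oracles in the test suite.

Binomial-logit equations use the Laplace approximation: an inner Newton
solve for the random-effect modes, an outer quasi-Newton optimization
over fixed effects and log SDs, and fixed-effect covariance from the
conditional information with the random-effect block solved out. On
shared test data the fit agrees with lme4-style Laplace estimates to
about four decimals; penalized-quasi-likelihood software of the
mid-2000s may differ in the second decimal. Complete separation
(constant response, a perfectly separating predictor, or a coefficient
running to the optimizer bound) raises a named error rather than
returning garbage.

**Degenerate replication.** When the response and every design column
are constant within the groups of some nesting level, rows are collapsed
to one per group and the deeper random levels dropped: the replicated
rows carry no information, and leaving them in sends the REML profile to
the boundary. This collapse reproduces the df bookkeeping of nest-level
analyses run on nestling tables (e.g. a timing-of-nesting equation at 60
nests has 57 residual df regardless of brood sizes).

**Denominator df** follow the containment (inner–outer) rule: each term
is assigned to the outermost level within whose groups it is constant,
and df at a level is (groups there) − (groups one level out) − (terms
assigned there). The intercept is accounted at the population level and
reported with the observation-level df, as in nlme; with no random
levels this reduces to OLS residual df. The original software's df rule
is not stated in most papers of the era; containment is the rule that
reproduces the published df patterns (nest-level terms tested against
nests, nestling-level terms against nestlings).

**Random-effect support.** 95% intervals for random-intercept SDs are
Wald intervals on the log-SD scale from a numerical Hessian of the
(restricted) likelihood. A level is called "supported" when its lower
bound clears 1% of the residual SD and the estimate is off the zero
boundary; boundary estimates are reported as [0, σ̂] with a warning. In
calibration simulations, a truly-zero group SD is called supported in
well under 10% of replicates and a group SD five times the residual SD in
essentially all of them.

**Standardization and interactions.** Path-analysis variables are
z-scored with the sample SD; squared terms square the standardized
column and are not re-standardized. Two-way interactions use Lance's
residualized cross products: the product of two standardized columns is
regressed on both main effects and the OLS residuals rescaled to SD 1,
making the interaction column exactly orthogonal to its main effects.

**Variance explained** follows the observed-vs-fitted convention:
squared correlation of observed and fitted values from a fixed-effects
-only refit (gaussian), or the R² of the ordinary regression of the
fixed-effects model's logit on the observed 0/1 response (binomial).

## Body composition

**Total body water.** The plateau mass-balance form: dilution space
N = W·(E_inj − E_plat)/(E_plat − E_bkg), TBW = N/k. Enrichments are
D₂O fractions; unit conversion from ppm or atom-percent is the caller's
concern. The exchange correction defaults to k = 1.04, the conventional
value for hydrogen exchange with non-aqueous molecules; the exact dose
and correction used in any particular field study belong to its own
protocol and are configurable. A plateau at or below background raises
a named error.

**Fat index.** A repeated-measures mixed model `mass ~ TBW + tarsus
[+ controls] + (1|individual)` is fitted and the index is
`mass − b_TBW·TBW`, centred and scaled to SD 1. Three deliberate choices:

1. *Marginal, not conditional, residuals.* Subtracting the individual
   BLUPs lets them absorb stable between-individual fat differences —
   exactly the biology the index is meant to carry; in simulation the
   conditional index's correlation with true fat collapses and
   between-individual coefficients shrink by half. The conditional
   version remains available (`level="conditional"`) and is what makes
   an individual's mean index shrink toward zero.
2. *Slopes estimated with condition covariates as controls.* Fat itself
   covaries with TBW through shared causes (date, moult, year, nestling
   traits); estimating the lean-mass slope without controlling for them
   biases it, leaving a spurious TBW component in the index that
   redistributes onto every TBW-loaded coefficient downstream (in
   simulation, a −0.06 bias on the moult→fat coefficient). The controls
   de-confound the slope but their own contributions are *not*
   subtracted from the index.
3. *Tarsus is controlled, not subtracted.* Removing an accurately
   estimated tarsus slope would delete precisely the size-related fat
   variation the fat structural equation estimates; the index is the
   mass variation unexplained by lean tissue, with size held fixed in
   the estimation step only.

**Moult** is an ordinal 1–4 score of body-moult completeness (quartile
bins); it enters structural equations as a numeric variable, with a
quadratic term only where an edge declares one.

## The synthetic study generator

The generator emulates the *structure* of a three-year island study:
~20 nests per year (mothers return with probability 0.5), clutch size
rounded normal (mean 4.17, SD 0.62, truncated ≥ 1), a brood manipulation
(±1 nestling) randomized over four-egg clutches, juveniles captured with
probability 0.45 and recaptured 2–11 times (mean ≈ 4), heavy-water
dilution at each capture, and Bernoulli first-year survival from a logit
linear in nestling mass and timing with a curvilinear tarsus term and
year/mother/nest random intercepts.

Ground truth is the published standardized coefficient set (e.g.
brood→mass −0.33, timing→mass −0.36, mass→fat 0.24, timing→moult −0.35,
moult→TBW −0.27 with quadratic −0.22, and the year contrasts). Two
small main effects the source analysis leaves unreported (timing→TBW,
date→TBW) are set to qualitative values (−0.05, −0.10). Random-intercept
SDs default to 0.3 on the standardized scale at every level — a
convention, not a published value. Raw-unit anchors (mass ≈ 18.5 ± 1.6 g,
tarsus ≈ 20.5 ± 0.8 mm, TBW ≈ 12 ± 1.2 g, season day ≈ 160 ± 12) are
invented scaffolding for realism.

The generator is built so that the configured coefficient *is* the
estimand of the analysis pipeline, by construction rather than
calibration-to-test:

- each endogenous variable's residual SD is topped up so its marginal
  variance is ~1, making re-standardized refits scale-consistent;
- downstream equations consume the *observed* (rounded, discretized,
  sample-standardized) parent columns, so predictor-side discretization
  causes no attenuation;
- response-side discretization is compensated: fledgling-count latent
  coefficients are pre-scaled by sd(count)/cov(latent, count) measured
  on a fixed large reference draw (rounding adds variance but also a
  sawtooth covariance; the manipulation adds independent ±1 moves), and
  the moult latent's coefficients are divided by the score–latent
  attenuation, refined by a short fixed-point iteration because the
  latent is not exactly normal;
- manipulated nests stay in the path-analysis sample. Excluding them
  would select on the brood-size response (only four-egg clutches are
  manipulated) and inflates the timing→brood coefficient by ~18%; the
  manipulation's extra mass effect is sized so the reduced-vs-control
  contrast equals the configured 1.2 g.

What the generator does **not** emulate: year-specific date slopes for
TBW and fat are encoded only through the declared date×timing
interaction (the year-interaction pattern of the source study is a sign
pattern, not a magnitude, and is off by default); no dispersal,
weather, radio-transmitter or supplementation effects; capture dates are
exchangeable rather than a within-season sampling design. Passing tests
therefore demonstrate that the pipeline recovers known structure under
realistic nesting, discretization and measurement noise — not that any
particular field dataset satisfies the model.

## Calibration measured under the defaults

With the default study size (≈60 nests, ≈110 captured juveniles, ≈460
captures), 100 replicates give pooled 95% CI coverage of 94.7% across
the 23 configured structural coefficients with every per-coefficient
mean bias below 0.02 SD. At a reduced size (12 nests/year), 500
replicates of the full basis-set test reject a true model at rate 0.062
(α = 0.05), with a near-uniform combined-p distribution. The acceptance
suite re-runs both checks at these sizes; the parameter-recovery
criterion is asserted on pooled coverage plus per-coefficient bias
because a per-coefficient threshold of 93/100 replicates is dominated by
binomial noise across 23 simultaneous coefficients even when coverage is
exactly nominal.

## Known limitations

- Random slopes, crossed random effects, non-logit links and
  Satterthwaite/Kenward–Roger df are out of scope.
- Claim p-values from the same dataset are not independent; Fisher's C
  treats them as such. The measured 6.2% null rejection suggests the
  approximation is adequate at these designs, but strongly overlapping
  claims could misbehave.
- The Laplace binomial SEs use the conditional information; profile or
  bootstrap intervals would be wider in small samples.
- The fat index inherits the identifiability limits of residual indices:
  effects of variables that act on mass *only* through lean tissue are
  not separable from the TBW slope.
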