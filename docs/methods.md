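# Methods

This note documents the models, conventions and numerical choices behind
`batlife`, module by module, together with what the synthetic-data generator
does and does not emulate.

## Individual-based generator (`batlife.synthetic`)

The simulator produces longitudinal records for female bats in philopatric
maternity colonies, censused once per summer. One row of causal structure
underlies everything downstream:

* **Adult size.** Forearm length (FAL, mm) is drawn once at the end of
  juvenile growth as
  `FAL = β0 + β_T·T_birth + β_C·C_birth + ε`, where `T_birth` is the mean
  minimum temperature (°C) of the critical mid-summer window (June 22 –
  July 16) of the birth year, `C_birth` the number of adult females in the
  natal colony that year, and `ε ~ N(0, σ)`. Values are clamped to a
  biological range (default 38–47 mm). There is no post-maturation growth
  trajectory: the field protocol this emulates uses a single adult spring
  measurement. Defaults: β0 = 38.0, β_T = 0.35 mm/°C, β_C = 0.01 mm/female,
  σ = 1.1 mm, temperatures N(12, 1)°C, chosen so the realized adult cohort
  is 42.7 ± 1.2 mm.

* **Annual reproduction.** From age 1 (first summer after birth), a female
  weans at most one pup per year with probability
  `logit p = −2.0 + 0.70·(FAL − 42.7) + 0.20·age + 0.015·(C − 27.5)`.
  Pup sex is i.i.d. Bernoulli with female fraction 0.518; only female pups
  are tracked longitudinally (males are solitary and enter the pedigree
  only).

* **Annual mortality.** After the breeding census of the same year
  (reproduce-then-survive; the alternative ordering is available as
  `event_order`), the female dies with probability
  `logit q = −2.9 + 0.22·age − 0.55·AFR + 5.0·F_t`,
  where AFR is her age at first reproduction and `F_t` her
  offspring-per-season rate to date; both are zero until first reproduction.
  The direct coefficient on size is 0 by default: size influences mortality
  *only* through the realized reproductive covariates. This mediated
  trade-off — larger females start earlier and reproduce more, and pay for
  it in survival — is the mechanism the downstream survival models are
  designed to detect.

The vital-rate defaults were calibrated once, against the generator's own
exact dynamic program (below), so that the cohort statistics sit in the
regime of a multi-decade field study of this species: mean adult FAL
42.7 ± 1.2 mm, roughly a third of complete-life females never reproducing,
mean lifetime reproductive success near 2 offspring, lifespan strongly
increasing with age at first reproduction, and a hump-shaped λ(size) whose
viable window (≈ 41–44.5 mm at realized colony density) lies within ±1.5 SD
of the size distribution. The window geometry matters: placing an endpoint
beyond 2 SD of the sizes makes it unestimable by any method at these sample
sizes.

Colonies are seeded with founder females (uniform ages 1..6, no pre-study
reproductive history) and run for `n_years`; females alive at the end are
right-censored. Censoring is study-end truncation only — philopatry is
perfect, there is no emigration. An optional catastrophic year adds a
configured logit boost to every hazard that year.

**Exact truth.** `TruthRecord` stores the generating coefficients and their
implied probability grids, and `exact_schedules(size, colony_size)` runs a
dynamic program over the reproductive-history state space
(AFR × offspring count) to return, exactly, the marginal age schedules a
cohort of that size experiences: state-independent `p(a)`, the
survivor-averaged hazard `q(a)`, survivorship to each breeding census, and
expected lifetime offspring. These are the oracles for all recovery tests.
Because the density term raises reproduction, truth comparisons against a
fitted dataset must be evaluated at that dataset's realized mean colony
size, not at the configured reference.

**Genotypes.** Each individual carries 13 unlinked microsatellite loci
(8 alleles each by default) with founder frequencies drawn from a flat
Dirichlet. Offspring inherit one maternal allele from the mother's *true*
genotype and one paternal allele from the population frequencies (fathers
are unsampled). Each reported allele call is independently replaced by a
frequency-weighted random allele with probability 0.01, a typical
microsatellite typing-error rate; inheritance always uses true alleles.

## Life-history traits (`batlife.life_history`)

AFR and LRS derive from mother–offspring links (the true pedigree, a dict,
or an accepted maternity-assignment table), matching how a genetic pedigree
rather than direct observation establishes reproduction in the field. A
female's life is *complete* when she was born into the study and her death
observed before study end; LRS-based analyses are restricted to complete
lives. Fecundity is LRS divided by the number of breeding seasons, which by
default counts every adult season (ages 1..max age); counting from first
reproduction is available (`breeding_seasons="since_first"`), as is
female-only offspring counting (`count_female_only`), since a study that
genotypes only female juveniles observes only female links.

The person-period table has one row per female-year with the death and
reproduction indicators, size centered on the analysis cohort's mean, the
colony-year census (an error, never imputation, if missing), the fixed
completed-life covariates (AFR, lifetime fecundity) and their causally
ordered time-varying counterparts (`afr_coded`, `fecundity_to_date`,
zero-coded before first reproduction — exactly the generator's coding, which
is what makes maximum-likelihood recovery of the generating coefficients
well-posed).

Headline percentages round to the nearest integer, other summaries to one
decimal. The lifespan-by-AFR comparison groups first reproduction at age 1,
age 2, and 3+, and uses the tie-corrected Kruskal–Wallis test; an all-tied
input returns H = 0 by convention.

## Penalized vital-rate models (`batlife.vital_rates`)

The fitter is a penalized IRLS GLM (binomial logit by default;
complementary log-log and Poisson log available):

* **Smooths** are P-splines: a cubic B-spline basis with `k` functions on
  quantile-placed knots, second-order difference penalty, and the
  sum-to-zero constraint absorbed by an SVD null-space reparameterization
  (k − 1 free coefficients per smooth). `k` is reduced with a warning when
  it exceeds the number of unique covariate values.
* **Grouping factors** (colony, year, birth year, individual) enter as
  ridge-penalized dummy blocks — the classical random-effect-as-penalty
  equivalence. No specialized mixed-model backend is used; this is the
  package's own implementation.
* **Smoothing selection** minimizes `deviance + 2·γ·EDF` (a UBRE-type
  criterion at unit scale) by cyclic coordinate descent over a log-spaced
  grid per penalized term, with warm-started IRLS; γ = 1.4 inflates the
  effective degrees of freedom to guard against overfitting. With
  `select=False` and `alpha=0` the fit is the exact unpenalized ML solution
  (verified against a Newton–Raphson oracle to 1e-6 and against mgcv).
* **Inference.** EDF is `tr[(XᵀWX + S)⁻¹XᵀWX]`; AIC = deviance + 2·EDF;
  deviance explained is relative to the intercept-only fit (exactly 0 for
  the null model). Smooth terms get Wald χ² tests on the Bayesian posterior
  covariance with EDF degrees of freedom, linear terms z-tests. These
  p-values are approximations (slightly liberal for smooths); the package
  reports them at the conventional 0.05 level without multiplicity
  correction.
* **Population-level prediction.** Excluding the group effects by setting
  their columns to zero biases marginal rates, because ridge-shrunken level
  effects need not average to zero. Predictions with
  `include_random=False` therefore fill each dummy block with the training
  level *frequencies* — the frequency-weighted average level — which removes
  the bias and propagates correctly into the delta-method intervals.
  Points outside the observed covariate support are clamped to the boundary
  and flagged.

The cost-of-reproduction mortality model restricts to complete lives that
reproduced at least once (so AFR is defined and fecundity is a realized
lifetime rate) and adds AFR and fecundity to the size/age smooths. Two
fecundity codings are provided: the completed-life rate
(`fecundity_mode="lifetime"`, the conventional analysis) and the
per-season rate realized up to each year (`"to_date"`, the causally ordered
alternative that matches the generating process exactly). The lifetime
coding is a proxy for the generating time-varying rate, so a residual
size-correlated signal remains; with enough person-years that residual
becomes statistically significant even though the direct size effect is
exactly zero. Tests therefore assert the robust forms: universal
*attenuation* of the size term under the lifetime coding, and median
non-significance under the to-date coding.

A sensitivity refit excluding one calendar year (e.g., one with
catastrophic winter mortality) reports coefficient and p-value deltas.

## Demography (`batlife.demography`)

`build_life_table` converts annual schedules over ages 1..x_max (default
x_max = 21, the species' maximum recorded age) into `l(x)`, `m(x)`.
Two census conventions are exposed:

* `post_breeding` (default): offspring are counted at the maternity roost
  before the overwinter hazard of the same age class, so
  `l(x) = s_juv · Π_{a=1..x−1}(1 − q(a))`. This matches the generator's
  reproduce-then-survive ordering and conserves mean simulated lifetime
  offspring exactly.
* `pre_breeding`: `l(x) = s_juv' · Π(1 − q(a))` up to and including age x,
  the textbook product form.

The two differ by one hazard factor per age; the difference is a timing
convention, not a substantive model choice. Juvenile (age-0) survival is
folded into l(1) via `first_year_survival` (default 1.0, consistent with
counting pups at the summer census — the adult models never estimate it);
the viable window shifts with this multiplier roughly as a uniform scaling
of R0, and the pipeline records the value used.

R0, T and λ use the standard definitions `R0 = Σ l m`,
`T = Σ x l m / R0`, `λ = exp(ln R0 / T)`, which make λ > 1 exactly
equivalent to R0 > 1 and make the growth-rate formula the textbook
Euler–Lotka approximation; an age-weighted variant of "R0" that circulates
in some treatments is available behind `r0_definition="as_printed"` for
comparison. The approximation is exact only for reproduction concentrated
at one age; `leslie_growth_rate` builds the corresponding Leslie matrix
(post-breeding census) whose dominant eigenvalue solves the Euler–Lotka
equation exactly, and agrees with the approximation to well under 5 % on
the generator's schedules.

`lambda_vs_size` evaluates both fitted vital-rate surfaces on a size grid
(default 40–45.5 mm in 0.5 mm steps — inside the observed size support),
builds a life table per size, and reports the maximal contiguous λ > 1 run
with endpoints refined by bisection on the continuous model predictions to
0.01 mm. No viable sizes returns an empty interval, not an error.

## Maternity assignment (`batlife.pedigree`)

Marker diagnostics use the standard closed forms: `He = 1 − Σp²`,
`PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ`, and the first-parent non-exclusion
probability `NE1 = 4a₂ − 2a₂² − 4a₃ + 3a₄` (aₙ = Σpⁿ), cross-checked to
1e-10 against exhaustive enumeration over HWE genotype pairs; HWE itself is
tested by χ² on genotype counts (df = genotypes − alleles). The combined
non-exclusion probability is the per-locus product and strictly decreases
as loci are added.

The LOD enumerates ordered true genotypes of mother and offspring under
HWE, Mendelian transmission with the paternal allele from population
frequencies, and an observation model in which each reported allele is
independently mis-scored (replaced by a frequency-weighted random allele)
with rate ε. Likelihood tables per locus are precomputed by three small
matrix products, so scoring is a table lookup. With ε = 0 an incompatible
pair returns −∞ (the sentinel minimum); with ε > 0 all LODs are finite and
decrease in the mismatch count. Zero-frequency alleles are floored at the
smallest positive frequency with a warning.

The strict-confidence delta threshold (best-minus-runner-up LOD) is
calibrated by vectorized Monte Carlo: simulated offspring with the true
mother present in a candidate pool of configurable size (default 20,
proportion sampled 1.0 — philopatry puts the mother in the pool whenever
alive), choosing the smallest delta at which at least 95 % of clearing
assignments are correct. An assignment is accepted at the strict level
and/or at zero mismatches. Null alleles are not modelled.

## Pipeline and configuration

A single YAML file (a `simulation:` block plus analysis settings) drives
the staged pipeline simulate → traits → fit → demography → pedigree; every
stage writes CSV/JSON under the run directory, and the manifest records a
config hash, the seed and SHA-256 of every output, so identical
config + seed reproduces identical bytes. The schema rejects out-of-range
probabilities, negative counts and unknown keys with explicit messages.
Prediction-model group effects default to colony and year; individual
identity is available as a grouping factor but multiplies the coefficient
count by the number of females, so the default keeps runs fast on a single
core.

## What the generator emulates, and what passing tests do not show

The generator reproduces the *statistical structure* assumed by the
analysis: size set by the early environment — temperature and density — then fixed;
history-dependent hazards; philopatric censusing; Mendelian markers with
typing error. It deliberately omits: male life histories and paternal
pedigree structure; dispersal and detection failure (censuses are perfect);
heritability of size; environmental stochasticity beyond the temperature
series; density regulation (colonies drift with λ); null alleles and
allelic dropout. Passing recovery tests therefore show the estimators work
when the field assumptions hold — not that real censuses are complete or
real markers error-free.

Three measured limitations are documented rather than hidden:

* **Tail attenuation.** Penalized-smooth selection with γ = 1.4 (mine and
  mgcv's REML alike, verified on identical data) flattens the mortality
  size smooth where sizes are sparse, biasing λ upward beyond ≈ +1.5 SD of
  the size distribution. Viable-window endpoints are therefore recovered to
  about half a grid step in the median across replicates, not per draw.
* **LRS compensation is partial by construction.** A hump-shaped λ(size)
  with R0 = 1 at both window endpoints forces an ≈ 9 % hump in expected
  lifetime offspring across the central size terciles, and completed-life
  selection (small females outlive the study more often) depresses the
  smallest tercile further. Tercile LRS means therefore differ by more than
  the between-replicate SD of those means at cohort scale, though by far
  less than the individual-level LRS SD. Exact compensation (flat R0 > 1)
  would contradict a finite viable window, since λ = exp(ln R0/T).
* **Approximate smooth-term p-values** (Wald on EDF degrees of freedom) are
  mildly liberal; conclusions that hinge on a borderline smooth p-value
  should be checked against a refit or mgcv.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own balance of precision and runtime on one core:
coefficient-sign recovery uses 50 (tests) or 20 (acceptance script)
replicates of ~3–5k person-years with unpenalized fits; 3-SE coefficient
recovery one ~10k replicate; the mechanism checks 8 cohort-scale replicates
plus 3 larger studies (20 colonies × 35 years, ~25k person-years) for the
viable-window comparison; Monte-Carlo oracles use 2×10⁵ simulated lifetimes
and 10⁴ calibration trios. The full test suite runs in a few minutes; the
acceptance script in well under one.
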