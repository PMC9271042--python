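# batlife

Size-dependent life-history analysis for long-lived bats.

Global warming makes Bechstein's bats (*Myotis bechsteinii*) grow to larger
adult sizes, and larger females die younger. `batlife` implements the full
analysis chain needed to ask whether such females compensate by living
faster: an individual-based simulator of longitudinal colony data with the
relevant causal structure, life-history trait extraction, smooth vital-rate
models in a discrete-time survival framework, life-table demography across
body sizes, and likelihood-based maternity assignment from microsatellite
genotypes. It is aimed at quantitative ecologists who want a tested, seeded,
end-to-end reference implementation of this pipeline — and a generator with
known truth against which the estimators can be validated.

## The models

**Vital rates.** With one row per female-year, the annual death indicator
follows a discrete-time hazard model and the annual weaning indicator a
binary reproduction model, both fitted as penalized additive logistic
regressions:

    logit q(a, s) = f_age(a) + f_size(s) + b_afr·AFR + b_fec·F + u_colony + u_year
    logit p(a, s) = g_age(a) + g_size(s) + u_colony + u_year

where `f`, `g` are P-splines (cubic B-splines, second-order difference
penalty; basis dimension k = 6 for explanatory fits, k = 10 for prediction
surfaces), AFR is the age at first reproduction, `F` the per-season
fecundity, and `u` ridge-penalized group effects. Smoothing parameters
minimize a UBRE-type criterion with effective degrees of freedom inflated by
gamma = 1.4; model comparison uses AIC on the penalized fit's EDF.

**Demography.** Predicted rates at each forearm length `s` feed a cohort
life table with survivorship `l(x)` and female maternity
`m(x) = p(x|s)·φ` (female fraction φ = 0.518), from which

    R0 = Σ l(x) m(x)        T = Σ x l(x) m(x) / R0        λ = exp(ln R0 / T)

give the net reproductive rate, generation time and per-year growth
multiplier. The size window with λ > 1 is located on a grid and its
endpoints refined by bisection to 0.01 mm; a Leslie-matrix dominant
eigenvalue provides the exact cross-check for the Euler–Lotka approximation.

**Pedigree.** Candidate mothers (females detected in the offspring's colony
and birth year) are scored by a LOD — the log-likelihood ratio of maternity
versus non-relationship, with the unsampled father marginalized over
population allele frequencies and per-allele typing error marginalized
exactly — and accepted at a strict confidence level calibrated by Monte
Carlo, and/or at zero mismatching loci.

## Worked example

```
batlife all --outdir demo --seed 11
cat demo/report.txt
```

prints

```
batlife run (seed 11)
========================================
complete-life females: 814 (20% never reproduced)
forearm length: 43.1 +/- 1.2 mm
lifetime reproductive success: 1.62 +/- 1.63
age at first reproduction: 2.1 +/- 1.6 y
mortality model with reproduction costs:
  deviance explained: 39.3%
  p-values: s(age)=7.64e-40, s(size_centered)=0.161, afr_covariate=7.76e-40, fecundity_covariate=1.45e-34
viable size window (lambda > 1): 40.38-44.04 mm
generation time range: 2.92-12.75 y
maternity assignment: 100.0% of 2013 offspring (97.0% correct)
```

Reading the output: the simulated cohort's body sizes (43.1 ± 1.2 mm) and
reproductive statistics are in the regime of a 25-year field study of four
colonies. In the cost-of-reproduction mortality model, age, age at first
reproduction and fecundity are highly significant while the size smooth is
not (p = 0.161) — mortality differences between sizes are carried by the
reproductive covariates. Generation time falls steeply with size, and only
females between 40.4 and 44.0 mm forearm length sustain population growth
(λ > 1). Machine-readable tables (`traits.csv`, `person_period.csv`,
`demography.csv`, `models.json`, `assignments.csv`, a hashed `manifest.json`)
are written alongside the report; identical config + seed reproduces
identical files.

The same pipeline is scriptable from Python:

```python
import batlife as bl

pop = bl.simulate_population(bl.SimulationConfig(seed=11))
traits = bl.compute_traits(pop.individuals_frame(), pop.events_frame(),
                           study_end_year=pop.study_end_year)
print(bl.cohort_summary(traits))
```

A YAML file with a `simulation:` block (and optional analysis settings —
grid, basis dimensions, assignment parameters) drives `batlife all
--config my.yaml`; see `batlife.pipeline.AnalysisConfig` for the schema.

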