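# cytoage

Age-dependent reference modelling of stimulated whole-blood cytokine
concentrations in children.

Cytokine-based assays (the interferon-γ release assay for tuberculosis being
the canonical example) perform worse in children than in adults, in part
because the capacity to release cytokines changes through childhood — yet
paediatric normal ranges for cytokine concentrations barely exist. `cytoage`
implements the statistical machinery needed to build such age-dependent
normal ranges from multiplex immunoassay data of a paediatric cohort (eight
cytokines — IL-1ra, IL-2, IL-4, IL-6, IL-10, IFN-γ, IP-10, TNF-α — measured
unstimulated and after whole-blood stimulation with SEB, PHA and
*C. albicans*), and a seeded synthetic-cohort generator so that every stage
is testable without access to patient data.

## The model

Concentrations are treated as lognormal around an age-dependent median
m(age). For subject *i* and measurement *j*:

    ln C_ij = ln m(age_i; β) + η_i + ε_ij,   η_i ~ N(0, ω²),  ε_ij ~ N(0, σ²)

with four candidate median functions

    M1 linear        m(a) = β₀ (1 + β₁ a)
    M2 exponential   m(a) = β₀ exp(β₁ a)          (reference model)
    M3 asymptote     m(a) = β_asym + (β₀ − β_asym) exp(−β₁ a)
    M4 logistic      sigmoid between β₀ and β_asym with inflection t50

all satisfying m(0) = β₀, the expected value in infancy. Immunoassay values
below the lower limit of quantification (LLOQ, 3.2 pg/mL; ×10 for the 1:10
diluted SEB/PHA conditions) are left-censored and contribute
Φ((ln LLOQ_eff − ln m − η)/σ) to the likelihood (the pharmacometric "M3"
censoring treatment); values above the ULOQ are extrapolated from the
calibration curve and enter as observed. The subject effect η is integrated
out by adaptive Gauss–Hermite quadrature, and models are compared by AIC with
a parsimony tie-break plus visual predictive checks. Derived quantities
follow the field's conventions: between-subject variability is reported as a
lognormal CV, 100·√(exp(ω²)−1); the change over 12 years as
100·(m(12)/m(0) − 1); age-specific percentile curves as
P_q(age) = m(age)·exp(z_q·ω).

The package also provides univariate censored linear (Tobit) regression on
log concentrations for covariate screening (age, weight-for-age z-score,
sex, vitamin D), tie-corrected Kendall correlations, censoring-aware summary
tables, and a five-stage pipeline
(simulate → summarize → screen → fit → centiles/VPC).

## Worked example

Simulate a 271-child cohort, fit the censored mixed-effects exponential age
model to SEB-stimulated TNF-α, and derive reference percentiles:

```bash
$ cytoage simulate --n 271 --seed 1 --out .
wrote subjects.csv and observations.csv

$ cytoage fit-mixed --input observations.csv --subjects subjects.csv \
      --cytokine TNF-a --condition SEB --seed 7 --out fit.json
M2_exponential: infancy 4433 pg/mL, 12 y 1.144e+04 pg/mL, change +158%, IIV CV 66% -> fit.json

$ cytoage centiles --fit fit.json --out centiles.csv
$ head -4 centiles.csv
age_years,level,value_pg_ml,basis,cytokine,condition
0,5,1644.05,between_subject,TNF-a,SEB
0,50,4433.19,between_subject,TNF-a,SEB
0,95,11954.1,between_subject,TNF-a,SEB
```

The fit says: the median SEB-stimulated TNF-α response is estimated at
~4400 pg/mL in infancy, rising ~2.6-fold by age 12, with a between-subject
coefficient of variation of 66% (the synthetic truth for this stratum is
4740 pg/mL, +129% and 66%; a single n=271 cohort estimates these with the
sampling noise visible here). The centiles file tabulates the 5th/50th/95th
percentile concentration on a 0–13 year grid — the age-dependent normal
range. `cytoage vpc` checks the fit by simulation:

```bash
$ cytoage vpc --fit fit.json --input observations.csv --subjects subjects.csv --out vpc.csv
band coverage per level — P5: 83%, P50: 83%, P95: 100%; wrote vpc.csv
```

i.e. the observed 5th/50th/95th percentiles fall inside their 90% simulated
bands in 5/6, 5/6 and 6/6 age bins. `cytoage run-all --seed 1 --out run/`
executes the whole pipeline over the full 32-stratum panel and renders a
markdown report with the summary table, the covariate-association matrix and
the fitted age-model table.

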