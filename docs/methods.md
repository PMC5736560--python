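# Methods

## Model and assumptions

All concentrations are assumed lognormal around an age-dependent median.
For subject *i*, measurement *j* within one cytokine × stimulation stratum:

    ln C_ij = ln m(age_i; β) + η_i + ε_ij
    η_i ~ N(0, ω²)   (between-subject, "inter-individual" variability)
    ε_ij ~ N(0, σ²)  (residual: assay noise + model misspecification)

Both random terms act additively on the natural-log scale, i.e.
multiplicatively on concentration — the conventional choice for
immunoassay data whose spread is reported as a CV. The age trend enters
only through the median; covariates other than age are screened separately
(below) and deliberately kept out of the mixed model.

Four median functions are implemented (`cytoage.models`):

| id | form | parameters | use |
|----|------|-----------|-----|
| M1_linear | β₀(1+β₁a) | β₀, β₁ | near-linear trends; β₁ > −1/13 so m > 0 on 0–13 y |
| M2_exponential | β₀·exp(β₁a) | β₀, β₁ | reference model; constant % change per year |
| M3_asymptote | β_asym + (β₀−β_asym)·exp(−β₁a) | β₀, β₁≥0, β_asym | trends flattening to a physiologic plateau |
| M4_logistic | sigmoid β₀→β_asym, rescaled so m(0)=β₀ | β₀, β₁≥0, β_asym, t50 | delayed-onset maturation |

Every form satisfies m(0) = β₀ exactly; "infancy" is operationalised as
age 0, so the tabulated change over 12 years is
100·(m(12)/m(0)−1), rounded half away from zero to an integer. The
logistic is rescaled, m(a) = β₀ + (β_asym−β₀)(L(a)−L(0))/(1−L(0)) with
L the standard logistic in age, because the raw four-parameter logistic
does not pass through β₀ at age 0; without the rescaling the "expected
value in infancy" would not be a model parameter.

Between-subject variability is reported as the exact lognormal CV,
100·√(exp(ω²)−1), not the small-ω approximation 100ω: fitted CVs in this
setting reach several hundred percent, far outside the linear regime (at
ω = 0.25 the two differ by ~3%; at ω = 1 by ~31%).

## Censoring

The immunoassay calibration range is 3.2–10 000 pg/mL; SEB- and
PHA-stimulated supernatants are analysed at 1:10 dilution, scaling both
limits tenfold. Values below the effective LLOQ are left-censored: the
stored value is the bound itself, flagged `below_lloq`, and the likelihood
uses the cumulative probability Φ((ln LLOQ_eff − ln m − η)/σ) — the
standard "M3" treatment of below-quantification data. Values above the
effective ULOQ are extrapolated from the calibration curve by the
instrument and are therefore treated as ordinary observations (flagged
`above_uloq_extrapolated`), not right-censored.

## Estimation

The marginal likelihood integrates η out per subject. The integrand is
log-concave in η, so each subject's posterior mode and curvature are found
by a damped Newton iteration and a Gauss–Hermite grid (21 nodes by
default) is centred and scaled there (adaptive quadrature). This is exact
when all of a subject's rows are uncensored (the integrand is then
Gaussian) and matches a 2001-point trapezoid integration to better than
1e-6 relative error on censored fixtures; raising 21 → 41 nodes changes
the optimum by < 1e-4. A pharmacometric engine's Laplace-type
approximation would be faster but less verifiable; at this problem size
(hundreds of subjects) quadrature costs well under a second per fit.

Optimisation is L-BFGS-B on transformed parameters (log β₀, log ω, log σ,
and form-specific transforms keeping each median valid), multi-start with
a data-driven initial point (naive log-linear regression with censored
rows at the bound) plus seeded perturbations, best likelihood kept.
Standard errors come from the central-difference Hessian of the marginal
log-likelihood, delta-method-transformed to the natural scale; a
non-positive-definite Hessian flags SEs unavailable instead of failing.
Because L-BFGS-B's success flag is unreliable with numeric gradients near
flat optima, convergence is finally judged by a first-order-condition
check.

**Identifiability of ω vs σ.** In the default fitting unit — one cytokine
× one condition — each subject contributes a single measurement, so ω and
σ enter the uncensored likelihood only through ω² + σ²; they are not
separately identifiable. `fit_model` therefore pins σ at 0.2 (≈ 20% CV,
the scale of the manufacturer-reported intra/inter-assay precision and
within the 9–25% residual-variability range typical for this design) when
no subject has replicates, and estimates ω. With replicate rows per
subject — e.g. the shared-η pooled mode, where one standard-normal subject
deviate per cytokine is scaled by each condition's ω — both components are
estimated. AIC counts only estimated parameters.

## Model selection

Candidates are ranked by AIC (2k − 2 lnL). Fits within ΔAIC < 2 of the
best are treated as statistically equivalent; among them the fewest
estimated parameters wins, and between equally-parameterised equivalents
the reference exponential form is preferred (then AIC). The practical
reading: the exponential stands unless a rival beats it decisively. Two
caveats, measured by simulation in the acceptance suite: (i) linear and
exponential trends are genuinely hard to separate at n ≈ 271 with one
measurement per child and between-subject CVs of 40–70% — the decisive
wrong-direction rate is ~5–10% regardless of noise level; (ii) AIC
retains a ~10% chance of promoting the 4-parameter logistic on null data
via boundary overfits. Selection output therefore always includes the full
ranking and per-model VPCs for human review rather than a bare winner.

The age-adjusted share of between-subject variance is computed against a
nested fit with β₁ fixed at 0: 100·(1 − ω²_with/ω²_without), floored at 0.

## Covariate screening (Tobit)

Associations of log concentration with age (per year), weight-for-age
z-score (per SD), sex (girls vs boys) and 25-OH-vitamin-D (per 10 nmol/L)
are screened stratum by stratum with univariate censored linear
regression: normal density for observed rows, normal CDF at the log bound
for censored rows, maximised by BFGS from an OLS start. Effects are
reported as 100·(exp(α₁)−1) percent per unit with two-sided Wald p-values;
p < 0.05 without multiplicity correction, by design — this is a screening
analysis, and the output marks direction and significance rather than
claiming confirmatory inference. Strata with > 50% of rows below the LLOQ
are skipped (marker "X"): a slope estimated mostly from censored mass is
not reportable. Kendall correlations are tie-corrected (τ-b).

Summary tables mirror clinical-laboratory reporting: quantiles are type-7
with censored rows tied at the bound, and any quantile falling inside the
censored mass — and the median whenever > 50% of rows are censored — is
printed as a "<3.2"-style token, never as a number.

## Percentile curves and VPC

Reference percentiles are closed-form, P_q(age) = m(age)·exp(z_q·s), on a
0–13 y grid (step 0.1), default levels 5/50/95. The default basis takes
s = ω (the distribution of subjects' underlying levels); a total basis
with s = √(ω²+σ²) (single future measurements, wider) is always exported
too, since which of the two a published percentile chart shows is often
ambiguous. A Monte-Carlo method (empirical percentiles of simulated
individuals per grid age) cross-checks the closed form. Curves are
sex-independent by design.

The visual predictive check simulates ≥ 100 replicate datasets at the
observed ages under the fitted model, applies the stratum's quantification
limits (censored rows placed at the bound, exactly as in the observed
data), and compares observed per-age-bin 5th/50th/95th percentiles with
the central 90% band of each percentile across replicates. Bins are
age-quantile-based (default 6) and bins with < 3 observations are merged
with a neighbour.

## Synthetic cohort

The generator (`cytoage.simulate`) emulates the structure the analysis
assumes, with defaults frozen to the study conditions it mimics:

- n = 271 children; ages truncated-lognormal on [0.1, 12.8] y with
  post-truncation quartiles solved to (3.5, 7.9); the implied median is
  ≈ 5.4 (target ≈ 5.3 — two parameters cannot hit three quantile targets
  under truncation).
- sex Bernoulli(0.74 boy); weight-for-age z-score N(0.25, 1.11²).
- vitamin D truncated-lognormal, median 54 nmol/L, IQR (40, 69), range
  [11, 142], coupled to age by a Gaussian copula targeting Kendall
  τ = −0.13 (younger children are supplemented).
- the concentration panel covers all 32 cytokine × condition strata with
  exponential age models back-solved from reference (infancy, 12-year)
  median pairs and between-subject CVs of 42–1412%; σ = 0.2 throughout.
  The four unstimulated low-abundance strata (IL-2/4/6/10) use a flat
  2 pg/mL median with CV 120%, giving heavily (~two-thirds) censored data.

What it does **not** emulate: assay plate/batch effects, non-lognormal
tails (no Box-Cox alternatives), covariate effects on concentrations
other than age (weight, sex, vitamin D and lifestyle columns are inert by
construction, matching a screening null), correlations between cytokines
beyond the optional shared-η mode, and age-dependent censoring artefacts.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, and calibration of their operating
characteristics at realistic noise — not robustness to real-world
violations of lognormality or independence.

## Numerical choices and degenerate inputs

- ω < 1e-10 collapses the marginal likelihood to η = 0 (no integration).
- Newton steps for the posterior mode are clipped to ±4ω for stability
  under heavy censoring; tolerance 1e-12, ≤ 60 iterations.
- percent changes round half away from zero; CV round-trips are exact.
- `fit_model` requires ≥ 10 subjects and at least one uncensored row;
  Tobit requires ≥ 3 uncensored rows and a non-constant covariate;
  all-censored strata raise instead of returning silence.
- Pipeline stage seeds derive from the master seed as
  (seed·1009 + stage_index) mod 2³¹; identical configs give byte-identical
  CSVs.

## Problem sizes used in the test suite

Simulation-based checks use the cohort size the generator defaults to
(n = 271) with 20–200 replicates per experiment (100 for parameter
recovery and selection consistency, 200 permutations for screening
calibration, 40 meta-replicates × 200 simulation replicates for the VPC
check), chosen as the smallest designs whose Monte-Carlo error is well
below the asserted tolerances.

## Known limitations

- Single-measurement strata cannot separate ω from σ (see above); the
  reported residual CV in that case restates the fixed assay value rather
  than an estimate.
- AIC-based selection between linear and exponential trends at this
  design's information content is imperfect by nature; the VPC is the
  intended complementary diagnostic.
- The M3 asymptote model nests a decreasing exponential only at the
  β_asym → 0 boundary, so likelihood-ordering comparisons hold up to
  optimizer tolerance there.
- No covariate-adjusted or sex-stratified percentiles; no smoothing-based
  (LMS/GAMLSS) centile alternatives.
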