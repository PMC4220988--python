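# Methods

## Scientific setting

Valproic acid (VPA) is monitored by sparse steady-state serum sampling in
routine care.  Long-term exposure is associated with elevation of serum
γ-glutamyltransferase (γ-GT), and the *SOD2* Val16Ala polymorphism —
Val/Val carriers have less efficient mitochondrial superoxide dismutase
import — is a plausible modifier of that exposure–toxicity relationship.
The package estimates the full chain dose → individual exposure →
probability of γ-GT elevation, stratified by genotype and intellectual
disability, using nonlinear mixed-effects models.

## Population PK model

Structural model: one compartment, first-order absorption with lag,
first-order elimination, parameterised as (Ka, CL/F, Vd/F, ALAG).  The
absorption lag is fixed at 3.00 h; with sparse steady-state data it is not
separately identifiable.  At steady state the profile is periodic, so the
closed form wraps the time since the last dose into one dosing interval;
the Ka = Ke degeneracy switches to the analytic `t·e^{-kt}` limiting form
at a relative tolerance of 1e-8.

Covariate model (the final structure): daily dose enters CL/F and Vd/F as
powers of dose normalised by 1000 mg/day (a round value near the cohort
mean of ~930 mg/day); female sex and co-administered carbamazepine,
clobazam, phenobarbital and phenytoin are multiplicative factors on CL/F.
Inter-individual variability is exponential.  The default fit estimates a
random effect on CL/F only: the generating variances for ALAG, Ka and Vd/F
are of order 1e-7 or smaller, and holding them at the engine floor (1e-10)
avoids singular curvature without changing the model.  Residual error is
proportional by default (an additive model is a configuration switch);
estimation is FOCE with interaction, i.e. the model is linearised in η at
each subject's empirical Bayes mode and the residual variance evaluated at
the conditional prediction.

Exposure is summarised as the 24-h steady-state area under the curve,
`AUC = daily dose / CL_i`, which is invariant to how the daily dose is
split across dosing intervals.

**Dosing interval.** The generator administers the sustained-release
formulation once daily (τ = 24 h).  This is the reading consistent with
sampling times since the last dose that span a full 24 hours; it also
leaves a measurable peak–trough fluctuation.  Under twice-daily splitting
of the same dose the steady-state curve is nearly flat (≈72–76 mg/L for a
typical subject), and we verified by simulation that Ka and Vd/F then
become essentially unidentifiable.  AUC, and therefore the entire PD
stage, is invariant to this choice.

## Exposure–response (PD) model

The endpoint is binary: serum γ-GT above an age- and sex-stratified upper
limit of normal (ULN), strictly — a value exactly at the limit is normal.
ULN tables are user-supplied input; the shipped default (paediatric band
below 16 years, adult male 70 IU/L, adult female 40 IU/L) is a synthetic
placeholder, not a clinical reference.  Measurements within the first six
months of therapy are excluded (records at exactly six months are kept) to
avoid transient start-of-therapy elevations; concentrations below the
1 mg/L limit of quantification are treated as suspected noncompliance and
excluded.

The linear-exposure logit is

    logit Pr_ij = BASE + θ_ID·ID_i + θ_VV·VV_i + SLOPE·AUC_i + η_i ,

with AUC in g·h/L (mg·h/L scaled by 1/1000 so that SLOPE·AUC is of order
one at therapeutic exposure), covariates additive on the logit scale (the
only reading compatible with a negative intercept and with odds-ratio
reporting), Ala/Ala and Val/Ala pooled as the reference genotype group
(Ala/Ala is too rare to resolve), and one Gaussian random intercept per
subject.  An Emax alternative, `Emax·AUC/(EC50+AUC)`, is available and
reduces to the linear model to first order when `SLOPE = Emax/EC50`.
Estimation is sequential (two-stage): individual AUCs are frozen from the
PK stage before the PD fit.

## Marginal-likelihood engine

One engine serves both models.  The inner problem (per-subject posterior
mode of η) is a damped Newton iteration, vectorised across subjects for
scalar η; subjects violating stationarity at the returned point are
flagged, and a fit with more than 5% flagged subjects is reported as
non-converged.  The outer optimizer is L-BFGS-B on log-transformed
positive parameters with the objective scaled per observation (this keeps
the first unit-Hessian step inside the model's sane region) and loose box
bounds to exclude overflow regimes.  The objective includes all 2π
constants, so values are directly comparable with quadrature and
closed-form references; only OFV differences between nested models are
interpreted.

For continuous data the objective is FOCE with interaction, evaluated with
a rank-one marginal covariance (Sherman–Morrison) per subject.  For binary
data the default is **adaptive Gauss–Hermite quadrature** (25 nodes,
centred and scaled at the Laplace mode).  A plain Laplace approximation is
implemented and retained as an option, but with the random-intercept
variance near its estimated value (ω² ≈ 12, i.e. an SD of 3.5 logits) and
fewer than three binary observations per subject it attenuates every fixed
effect several-fold — simulate-and-refit showed an intercept of about −1.9
recovered for a generating −6.63.  Quadrature removes this bias entirely
and reproduces `lme4::glmer` (nAGQ = 25) to four significant figures on a
fixture dataset; the Laplace and quadrature objectives agree to 1e-3 in
the small-ω² regime where the expansion is valid, which the engine tests
pin down.  Probabilities are clamped to [1e-12, 1-1e-12] inside the
likelihood.

Standard errors, when requested, come from a central-difference Hessian of
the outer objective with delta-method back-transformation.

## Covariate selection

Greedy forward inclusion (largest significant ΔOFV first, candidate order
breaking ties) followed by backward elimination (smallest ΔOFV removed
while non-significant), with χ² thresholds computed from the 95th
percentile at 1 df (3.84) and 2 df (5.99; three-level covariates coded as
two indicators).  Candidates are applied by cloning the estimator with a
modified covariate tuple, so the same machinery drives PK and PD model
building.  Multicollinearity pruning (e.g. removing age, body weight and
enzyme-inducer terms that travel together with disability) is a
judgement call and therefore an explicit user-supplied exclusion list, not
an automated step.

## Validation machinery

*Bootstrap*: whole subjects are resampled with replacement, preserving
per-stratum subject counts; replicates without successful minimisation are
excluded from the percentile summaries, and a result with fewer than half
successful is flagged unreliable.

*VPC*: outcomes are re-simulated at the observed design (new random
intercepts, Bernoulli outcomes); observed proportions per stratum ×
exposure-quantile bin (default 4 bins of model-predicted AUC; dose binning
is a config option) are compared with the 5th–95th percentile band of the
simulated proportions.

*GOF*: population predictions at η = 0, individual predictions at the
empirical Bayes mode, and conditional weighted residuals
`CWRES = V^{-1/2}(y − F + G·η̂)` with `V = diag(σ²F²) + ω²GG'` per subject
(plain weighted residuals are the fallback for singular V).

## Synthetic cohort generator

The generator defines the study conditions: 237 subjects with ~3.5 sparse
steady-state concentrations each for the PK stage, 169 subjects with ~2.8
binary γ-GT visits each for the PD stage.  Covariates are drawn i.i.d.
from the reported marginals — sex (60.4% male in the PD preset),
intellectual disability (57.4%), *SOD2* genotypes (77.6/20.7/1.7%),
GSTM1/GSTT1 null (56.8%/47.9%), CYP2C9*3 and CYP2C19 variant alleles under
Hardy–Weinberg equilibrium, daily dose moment-matched lognormal truncated
to 100–2600 mg/day and rounded to 100 mg, age lognormal truncated to the
reported range, and body weight a monotone growth-curve function of age
with lognormal noise calibrated to the reported marginal moments.
Enzyme-inducing co-medication (CBZ, PB, PHT) is twice as frequent in
subjects with intellectual disability, preserving the marginal
frequencies; other co-medications are independent.  Sampling times are
uniform over 24 h since the last dose; concentration noise is proportional
with negative multipliers redrawn; binary outcomes use one random
intercept per subject and visits at ≥ 6 months.  A numeric γ-GT value
consistent with each binary outcome and its ULN band is attached so that
records survive CSV round trips.

The generator reproduces the reported marginal structure but not features
it does not model: no dose titration or longitudinal dose changes, no
dropout or visit-schedule realism beyond counts, no within-subject
concentration autocorrelation, and the covariate joint distribution beyond
the disability–inducer association is a product of marginals.  Recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data violations of
them.

Generating truth defaults to the published final estimates — PK: Ka 0.109
h⁻¹, CL/F 0.559 L/h, Vd/F 21.4 L, dose exponents 0.596 (CL) and 1.52
(Vd), factors 0.917 (female), 1.19 (CBZ), 0.906 (CLB), 1.12 (PB), 1.43
(PHT), ω²_CL 0.0587, σ² 0.0617; PD: BASE −6.63, disability 3.62, Val/Val
1.96, slope 1.55 per g·h/L, ω² 12.3.  The final-estimate ω² (not the
bootstrap median 3.48, which remains a preset) also drives the risk
simulation: with ω² = 12.3 the simulated odds-ratio pattern at 800 mg/day
(2.3 / 4.6 / 10.0) matches the published dose-risk table, while 3.48
yields much larger ratios.

## Risk simulation

For each dose × disability × genotype cell, replicates of n reference
individuals (male, no co-medication) are drawn: η_CL determines AUC, a
logit intercept η determines the event probability, and the cell
percentage is the mean probability.  Odds ratios are formed per replicate
against the same-dose reference cell and summarised as the replicate mean
with a 2.5–97.5 percentile interval (the published uncertainty
construction is unstated; replicate-level percentiles are the natural
Monte-Carlo analogue).  Defaults: 200 replicates × 1000 individuals, with
Monte-Carlo standard errors reported so dose-to-dose fluctuation is
quantifiable.  With all variances zero the cell percentage equals the
closed-form inverse logit, which the tests use as an oracle; the marginal
odds ratio is always attenuated towards 1 relative to the conditional
`e^coef`.

## Verification scales and known limitations

The acceptance experiments run at the study scale (237/827 PK, 169/472
PD).  The test suite uses 10 replicates per recovery experiment and the
acceptance script 30, chosen for Monte-Carlo precision of the replicate
means; reduced scales elsewhere (bootstrap study 15 cohorts × 40
resamples on 60-subject cohorts; VPC coverage 40 seeds × 150 simulated
datasets; risk ordering 500 individuals × 40 replicates) keep each check
fast while leaving binomial/Monte-Carlo error well inside the asserted
tolerances.

Known limitations:

* **Vd/F is weakly identified** under sparse steady-state sampling: its
  single-replicate maximum-likelihood estimate is heavy-tailed (roughly
  5–65 L across seeds, consistent with the very wide published bootstrap
  interval for this parameter and with the absence of reported standard
  errors for the final PK model).  Replicate means settle near the
  generating 21.4 L, with Monte-Carlo error of a few litres at 30
  replicates; Ka is wider still and is not a reported quantity.
* Binary-endpoint recovery at ω² ≈ 12 has wide per-replicate spread
  (matching the large reported relative standard errors); means over 30
  replicates recover the generating coefficients to within a few percent.
* The engine supports multi-dimensional diagonal random effects through a
  slower per-subject path; the vectorised path, used by both production
  models, is scalar-η.
* Exact reproduction of the published risk-table percentages is not
  expected: they depend on covariate-model scalings that are not fully
  recoverable; the contract is the closed-form zero-variability limit, the
  cell ordering, and the odds-ratio pattern.
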