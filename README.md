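# vpapkpd

Population pharmacokinetic–pharmacodynamic (PK–PD) modelling of valproic
acid (VPA) exposure and the risk of serum γ-glutamyltransferase (γ-GT)
elevation in epilepsy patients, with pharmacogenetic (*SOD2* Val16Ala)
stratification.

Long-term VPA therapy is associated with liver enzyme elevation, and the
mitochondrial antioxidant genotype *SOD2* Val/Val appears to amplify the
exposure–toxicity relationship.  This package implements the full analysis
pipeline a pharmacometrician would run on such data:

1. **Population PK** — a one-compartment oral model with absorption lag for
   sustained-release VPA, fitted to sparse steady-state therapeutic drug
   monitoring data by first-order conditional estimation with interaction
   (FOCE-I).  The covariate model is
   `CL/F = θ_CL · (Dose/1000)^θ_dose · θ_female^[female] · θ_CBZ^[CBZ] · … · e^η`,
   with an analogous dose power on `Vd/F`.
2. **Exposure–response (PD)** — a mixed-effects logistic model for the
   binary endpoint "γ-GT above the age/sex upper limit of normal":
   `logit Pr = BASE + θ_ID·ID + θ_VV·ValVal + SLOPE·AUC + η`,
   where `AUC = daily dose / CL_i` (g·h/L) is the individual steady-state
   exposure frozen from the PK stage, and η is a per-subject random
   intercept.  The binary marginal likelihood is computed by adaptive
   Gauss–Hermite quadrature (a plain Laplace approximation is available).
3. **Model building and validation** — forward-inclusion/backward-elimination
   covariate selection on objective-function changes (ΔOFV ≥ 3.84 for 1 df,
   5.99 for 2 df), stratified nonparametric bootstrap, visual predictive
   checks, and goodness-of-fit diagnostics (CWRES).
4. **Risk simulation** — Monte-Carlo prediction of the percentage of
   patients with γ-GT elevation and odds ratios by daily dose × *SOD2*
   genotype × intellectual disability.

Because the underlying patient data are not publicly deposited, the package
ships a first-class synthetic-cohort generator that reproduces the study's
covariate distributions, genotype frequencies (Hardy–Weinberg checked),
sparse sampling design and noise models, so the whole pipeline is testable
by simulate-and-refit parameter recovery.

## Worked example

```python
from vpapkpd.synthetic import pd_cohort_config, generate_full_cohort
from vpapkpd.pk_model import DEFAULT_PK_TRUTH, DEFAULT_PK_VARIANCE, PopulationPKModel
from vpapkpd.pd_model import DEFAULT_PD_TRUTH, GGTElevationModel, build_pd_table
from vpapkpd.dataset import Cohort, flag_noncompliance, filter_early_ggt
from vpapkpd.risk import simulate_risk

cohort, _ = generate_full_cohort(pd_cohort_config(), DEFAULT_PK_TRUTH,
                                 DEFAULT_PK_VARIANCE, DEFAULT_PD_TRUTH, seed=42)
kept, _ = flag_noncompliance(cohort.pk_records)      # drop sub-LOQ samples
ggt = filter_early_ggt(cohort.ggt_records)           # drop first 6 months
cohort = Cohort(cohort.subjects, kept, ggt)

pk = PopulationPKModel().fit(cohort)                 # FOCE-I
table = build_pd_table(cohort, pk.auc_)              # freeze individual AUCs
pd_fit = GGTElevationModel().fit(table)              # adaptive quadrature
risk = simulate_risk(DEFAULT_PK_TRUTH, pd_fit.to_pd_parameters(), [800.0],
                     omega2_cl=pk.omega2_["cl"], seed=42)
```

On this 169-subject synthetic cohort the run prints:

```
PK: CL/F=0.533 L/h  Vd/F=15.8 L  dose exp=0.628  PHT=1.42  omega2_CL=0.0575  sigma2=0.0644
PD: BASE=-9.52  ID=4.73  SOD2 Val/Val=2.38  slope=2.74 per g*h/L  omega2=16.3
disability       sod2_group  pct_elevated  odds_ratio  or_ci_low  or_ci_high
         - ValAla_or_AlaAla         14.01        1.00       1.00        1.00
         -           ValVal         28.80        2.49       2.33        2.63
         + ValAla_or_AlaAla         48.22        5.73       5.21        6.25
         +           ValVal         68.43       13.36      11.80       14.75
```

Reading this: the typical apparent clearance is 0.53 L/h with a power
dose effect (higher daily doses clear relatively faster, so exposure grows
sub-proportionally) and a 1.42-fold clearance increase under phenytoin
co-medication.  On the logit scale, intellectual disability and the *SOD2*
Val/Val genotype raise the intercept by 4.7 and 2.4 units, and each extra
g·h/L of daily exposure adds 2.7 units.  At 800 mg/day the model predicts
14% of reference patients (Ala-carrier, no disability) with elevated γ-GT,
rising to 68% (odds ratio 13.4) for Val/Val patients with intellectual
disability — single-cohort estimates scattered around the generating
values, as quantified by the recovery experiments below.

A CLI mirrors the pipeline stages:

```bash
vpa-pkpd run-all --outdir runs/demo --seed 7
vpa-pkpd simulate-risk --doses 400,800,1200 --outdir runs/risk --seed 7
```

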