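"""Synthetic cohort generator emulating the study population's structure.

Generates covariate tables, sparse steady-state VPA concentrations and binary
gamma-GT outcomes with the statistical features the analysis assumes: a
paediatric-to-adult epilepsy cohort on once-daily sustained-release VPA,
sparse therapeutic-drug-monitoring sampling spread over 24 h, genotype
frequencies at Hardy-Weinberg proportions, and co-medication that is more
common in subjects with intellectual disability.

Two presets mirror the published cohort summaries: ``pk_cohort_config()``
(237 subjects, ~3.5 concentrations each) and ``pd_cohort_config()`` (169
subjects, ~2.8 gamma-GT visits each).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import (
    Cohort,
    ConcentrationRecord,
    GGTRecord,
    SubjectCovariates,
    ULNTable,
    DAYS_PER_MONTH,
    default_uln_table,
)
from .pd_model import AUC_SCALE, PDParameters, event_probability, logit_linear
from .pk_model import PKThetas, PKVariance, Regimen, PKIndividual, concentration

__all__ = [
    "GeneratorConfig",
    "pk_cohort_config",
    "pd_cohort_config",
    "generate_cohort",
    "simulate_concentrations",
    "simulate_ggt_events",
    "generate_full_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults match the PK-PD subcohort."""

    n_subjects: int = 169
    sex_female: float = 0.396
    disability: float = 0.574
    sod2: tuple = (0.776, 0.207, 0.017)  # Val/Val, Val/Ala, Ala/Ala
    cyp2c9_star3_allele: float = 0.032
    cyp2c19_star2_allele: float = 0.293
    cyp2c19_star3_allele: float = 0.112
    gstm1_null: float = 0.568
    gstt1_null: float = 0.479
    comeds: dict = field(default_factory=lambda: {
        "CBZ": 0.199, "CLB": 0.190, "PB": 0.059, "PHT": 0.095,
        "TPM": 0.061, "ZNS": 0.057, "GBP": 0.011,
    })
    #: enzyme-inducer co-medication is more frequent with intellectual
    #: disability; prevalence in the disabled group is double the
    #: non-disabled group while preserving the marginal frequency
    inducer_disability_ratio: float = 2.0
    dose_mean: float = 903.8  # mg/day
    dose_sd: float = 502.7
    dose_range: tuple = (100.0, 2600.0)
    dose_step: float = 100.0  # clinical dosing granularity
    age_mean: float = 18.0  # years
    age_sd: float = 7.8
    age_range: tuple = (3.0, 52.2)
    weight_mean: float = 51.0  # kg
    weight_sd: float = 20.1
    #: once-daily sustained-release dosing, consistent with sampling times
    #: since the last dose spanning a full 24 h; AUC and the PD stage are
    #: invariant to how the daily dose is split
    tau: float = 24.0
    conc_samples: tuple = (2, 5)  # per-subject count, uniform inclusive
    sampling_window: float = 24.0  # h since last dose
    ggt_visits_base: int = 1  # visits = base + Binomial(n, p)
    ggt_visits_binom: tuple = (4, 0.45)  # mean 1 + 1.8 = 2.8
    followup_months: tuple = (6.0, 80.0)

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.sod2) - 1.0) > 1e-9:
            raise ValueError("SOD2 genotype frequencies must sum to 1")
        probs = [self.sex_female, self.disability, self.gstm1_null,
                 self.gstt1_null, self.cyp2c9_star3_allele,
                 self.cyp2c19_star2_allele, self.cyp2c19_star3_allele,
                 *self.sod2, *self.comeds.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.dose_range[0] >= self.dose_range[1]:
            raise ValueError("infeasible dose truncation range")
        if not (self.dose_range[0] < self.dose_mean < self.dose_range[1]):
            raise ValueError("dose_mean outside the truncation range")
        if not (self.age_range[0] < self.age_mean < self.age_range[1]):
            raise ValueError("age_mean outside the truncation range")


def pk_cohort_config() -> GeneratorConfig:
    """Preset matching the concentration-analysis cohort summaries."""
    return GeneratorConfig(
        n_subjects=237, sex_female=0.422, disability=0.553,
        comeds={"CBZ": 0.230, "CLB": 0.155, "PB": 0.088, "PHT": 0.106,
                "TPM": 0.053, "ZNS": 0.071, "GBP": 0.010},
        dose_mean=934.3, dose_sd=540.2, age_mean=17.2, age_sd=8.3,
        age_range=(2.2, 52.2), weight_mean=48.8, weight_sd=20.9,
    )


def pd_cohort_config() -> GeneratorConfig:
    """Preset matching the gamma-GT-analysis cohort summaries (the default)."""
    return GeneratorConfig()


def _truncated_lognormal(rng, mean, sd, lo, hi, size):
    """Lognormal matched to (mean, sd) by moments, rejection-truncated to [lo, hi]."""
    if not (lo < mean < hi):
        raise ValueError("infeasible truncation: mean outside range")
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.lognormal(mu, math.sqrt(s2), todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _weight_from_age(rng, age, mean, sd):
    """Monotone growth-curve median with lognormal noise, rescaled to the
    target marginal mean/SD; only the marginals are calibrated."""
    median = 72.0 * age**1.6 / (age**1.6 + 13.0**1.6)
    noise = rng.lognormal(0.0, 0.18, size=age.shape)
    w = median * noise
    w = w * (mean / w.mean())
    return np.clip(w, 6.0, 135.0)


def _hwe_genotype(rng, q, n):
    """Genotype counts of the variant allele under HWE: returns 0/1/2 copies."""
    return rng.binomial(2, q, size=n)


def generate_cohort(config: GeneratorConfig, seed) -> Cohort:
    """Draw a covariates-only cohort (no concentration or gamma-GT records)."""
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    width = max(3, len(str(n)))
    female = rng.random(n) < config.sex_female
    disability = rng.random(n) < config.disability
    sod2_idx = rng.choice(3, size=n, p=np.asarray(config.sod2))
    sod2 = np.array(["ValVal", "ValAla", "AlaAla"])[sod2_idx]
    c9 = _hwe_genotype(rng, config.cyp2c9_star3_allele, n)
    cyp2c9 = np.array(["*1/*1", "*1/*3", "*3/*3"])[c9]
    # CYP2C19 groups from the two variant alleles jointly under HWE
    q_var = config.cyp2c19_star2_allele + config.cyp2c19_star3_allele
    c19 = _hwe_genotype(rng, q_var, n)
    cyp2c19 = np.array(["homEM", "hetEM", "PM"])[c19]
    gstm1 = np.where(rng.random(n) < config.gstm1_null, "null", "present")
    gstt1 = np.where(rng.random(n) < config.gstt1_null, "null", "present")

    age = _truncated_lognormal(rng, config.age_mean, config.age_sd,
                               *config.age_range, n)
    weight = _weight_from_age(rng, age, config.weight_mean, config.weight_sd)
    dose = _truncated_lognormal(rng, config.dose_mean, config.dose_sd,
                                *config.dose_range, n)
    if config.dose_step:
        dose = np.clip(np.round(dose / config.dose_step) * config.dose_step,
                       *config.dose_range)

    inducers = {"CBZ", "PB", "PHT"}
    pi = config.disability
    r = config.inducer_disability_ratio
    comed_flags = {}
    for drug, m in config.comeds.items():
        if drug in inducers and r != 1.0:
            p0 = m / (1.0 - pi + r * pi)
            p = np.where(disability, min(r * p0, 1.0), p0)
        else:
            p = np.full(n, m)
        comed_flags[drug] = rng.random(n) < p

    start = _dt.date(2000, 1, 1)
    subjects = []
    for i in range(n):
        comeds = frozenset(d for d in config.comeds if comed_flags[d][i])
        subjects.append(
            SubjectCovariates(
                subject_id=f"S{i:0{width}d}",
                age=float(age[i]),
                sex="female" if female[i] else "male",
                body_weight=float(weight[i]),
                daily_dose=float(dose[i]),
                sod2=str(sod2[i]),
                cyp2c9=str(cyp2c9[i]),
                cyp2c19=str(cyp2c19[i]),
                gstm1=str(gstm1[i]),
                gstt1=str(gstt1[i]),
                intellectual_disability=bool(disability[i]),
                comeds=comeds,
                vpa_start_date=start + _dt.timedelta(days=int(rng.integers(0, 3653))),
            )
        )
    return Cohort(subjects=subjects, pk_records=[], ggt_records=[])


def _draw_individuals(cohort, thetas: PKThetas, variance: PKVariance, rng):
    """Per-subject individual PK parameters with exponential random effects."""
    from .pk_model import individual_parameters

    individuals = {}
    for s in cohort.subjects:
        eta = {p: rng.normal(0.0, math.sqrt(w2)) if w2 > 0 else 0.0
               for p, w2 in variance.omega2.items()}
        individuals[s.subject_id] = individual_parameters(thetas, s, eta)
    return individuals


def simulate_concentrations(
    cohort: Cohort,
    thetas: PKThetas,
    variance: PKVariance,
    seed,
    config: GeneratorConfig | None = None,
):
    """Sparse steady-state concentration records with proportional error.

    Returns ``(records, truth)`` where ``truth`` maps subject_id to a dict
    with the individual's realised clearance and 24-h AUC (mg*h/L) — the
    quantities a sequential PK->PD analysis would freeze.
    """
    config = config or pd_cohort_config()
    rng = np.random.default_rng(seed)
    individuals = _draw_individuals(cohort, thetas, variance, rng)
    sigma = math.sqrt(variance.sigma2)
    records = []
    truth = {}
    lo, hi = config.conc_samples
    for s in cohort.subjects:
        ind = individuals[s.subject_id]
        truth[s.subject_id] = {"cl_i": ind.cl_i, "auc": s.daily_dose / ind.cl_i}
        n_obs = int(rng.integers(lo, hi + 1))
        dose_admin = s.daily_dose * config.tau / 24.0
        regimen = Regimen(dose_per_admin=dose_admin, tau=config.tau, steady_state=True)
        times = rng.uniform(0.0, config.sampling_window, n_obs)
        for t in times:
            pred = concentration(float(t), regimen, ind)
            mult = 1.0 + rng.normal(0.0, sigma) if sigma > 0 else 1.0
            while mult <= 0:  # redraw the rare negative multiplier
                mult = 1.0 + rng.normal(0.0, sigma)
            records.append(
                ConcentrationRecord(
                    subject_id=s.subject_id,
                    time_after_last_dose=float(t),
                    dose_per_administration=dose_admin,
                    dosing_interval=config.tau,
                    value=float(pred * mult),
                )
            )
    return records, truth


def simulate_ggt_events(
    cohort: Cohort,
    pd_params: PDParameters,
    auc_by_subject: dict,
    seed,
    config: GeneratorConfig | None = None,
    uln: ULNTable | None = None,
):
    """Binary gamma-GT outcomes: one random intercept per subject, Bernoulli
    visits at months >= 6.

    ``auc_by_subject`` carries the individual 24-h AUC in mg*h/L (the PK
    truth in a simulation study, or frozen PK empirical Bayes values).  A
    numeric gamma-GT value consistent with the binary outcome and the ULN
    band is attached so the records survive a CSV round trip.
    """
    config = config or pd_cohort_config()
    uln = uln or default_uln_table()
    rng = np.random.default_rng(seed)
    records = []
    n_vis, p_vis = config.ggt_visits_binom
    for s in cohort.subjects:
        eta = (rng.normal(0.0, math.sqrt(pd_params.omega2_logit))
               if pd_params.omega2_logit > 0 else 0.0)
        auc_scaled = float(auc_by_subject[s.subject_id]) * AUC_SCALE
        logit = logit_linear(pd_params, auc_scaled,
                             int(s.intellectual_disability), s.sod2_valval, eta)
        prob = float(event_probability(logit))
        n_visits = config.ggt_visits_base + int(rng.binomial(n_vis, p_vis))
        limit = uln.lookup(s.sex, s.age)
        lo_m, hi_m = config.followup_months
        for _ in range(n_visits):
            months_days = int(rng.integers(round(lo_m * DAYS_PER_MONTH),
                                           round(hi_m * DAYS_PER_MONTH)))
            event = int(rng.random() < prob)
            if event:
                value = limit * (1.0 + rng.lognormal(-0.3, 0.8))
            else:
                value = limit * rng.uniform(0.2, 1.0)
            date = s.vpa_start_date + _dt.timedelta(days=months_days)
            records.append(
                GGTRecord(
                    subject_id=s.subject_id,
                    measurement_date=date,
                    value=float(value),
                    months_since_vpa_start=months_days / DAYS_PER_MONTH,
                    elevated=event,
                )
            )
    return records


def generate_full_cohort(
    config: GeneratorConfig,
    pk_truth: PKThetas,
    pk_variance: PKVariance,
    pd_truth: PDParameters,
    seed,
    uln: ULNTable | None = None,
):
    """Covariates + concentrations + gamma-GT events from one master seed.

    Returns ``(cohort, truth)``; child seeds are spawned deterministically so
    each stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_conc, s_ggt = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    cohort = generate_cohort(config, s_cov)
    conc, truth = simulate_concentrations(cohort, pk_truth, pk_variance, s_conc, config)
    auc = {sid: v["auc"] for sid, v in truth.items()}
    ggt = simulate_ggt_events(cohort, pd_truth, auc, s_ggt, config, uln)
    return Cohort(cohort.subjects, conc, ggt), truth
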