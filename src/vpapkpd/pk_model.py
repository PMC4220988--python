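"""One-compartment oral PK model for sustained-release valproic acid.

Structural model: first-order absorption with a lag time, first-order
elimination, parameterised by apparent clearance CL/F, apparent volume Vd/F,
absorption rate constant Ka and lag ALAG.  Inter-individual variability is
exponential.  The covariate model multiplies the typical clearance by a power
of the dose normalised to a reference (1000 mg/day) and by one factor per
categorical covariate (female sex and co-administered enzyme modulators);
apparent volume carries its own dose power.

Steady-state exposure is summarised by the 24-hour area under the curve,
AUC = daily dose / CL_i, which is invariant to how the daily dose is split
across dosing intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SubjectCovariates

__all__ = [
    "PKThetas",
    "PKVariance",
    "PKIndividual",
    "Regimen",
    "DEFAULT_PK_TRUTH",
    "DEFAULT_PK_VARIANCE",
    "DOSE_REF",
    "individual_parameters",
    "concentration",
    "auc_ss",
    "conc_profile",
]

#: reference daily dose (mg/day) for the power covariate model; near the
#: cohort mean daily dose (~930 mg/day), rounded for readability.
DOSE_REF = 1000.0

#: relative tolerance below which ka and ke are treated as tied and the
#: analytic limiting form is used
KA_KE_RTOL = 1e-8


@dataclass(frozen=True)
class PKThetas:
    """Typical-value fixed effects of the population PK model."""

    ka: float  # 1/h
    cl: float  # L/h at the reference covariates
    vd: float  # L at the reference covariates
    alag: float = 3.0  # h, fixed
    dose_exp_cl: float = 0.0
    dose_exp_vd: float = 0.0
    factor_female: float = 1.0
    factor_cbz: float = 1.0
    factor_clb: float = 1.0
    factor_pb: float = 1.0
    factor_pht: float = 1.0

    def __post_init__(self):
        for name in ("ka", "cl", "vd", "factor_female", "factor_cbz",
                     "factor_clb", "factor_pb", "factor_pht"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PKVariance:
    """Inter-individual (exponential) variances and residual variance."""

    omega2: dict = field(default_factory=dict)  # keys among {alag, ka, vd, cl}
    sigma2: float = 0.0  # proportional residual variance

    def __post_init__(self):
        if any(v < 0 for v in self.omega2.values()) or self.sigma2 < 0:
            raise ValueError("variances must be non-negative")


#: literature-reported final population estimates for sustained-release VPA in
#: an epilepsy cohort; used as the default generating truth for synthetic data.
DEFAULT_PK_TRUTH = PKThetas(
    ka=0.109, cl=0.559, vd=21.4, alag=3.0,
    dose_exp_cl=0.596, dose_exp_vd=1.52,
    factor_female=0.917, factor_cbz=1.19, factor_clb=0.906,
    factor_pb=1.12, factor_pht=1.43,
)

DEFAULT_PK_VARIANCE = PKVariance(
    omega2={"alag": 4.48e-9, "ka": 7.77e-7, "vd": 1.83e-7, "cl": 0.0587},
    sigma2=0.0617,
)


@dataclass(frozen=True)
class PKIndividual:
    """Parameters of one subject after covariates and random effects."""

    ka_i: float
    cl_i: float
    vd_i: float
    alag_i: float

    def __post_init__(self):
        for name in ("ka_i", "cl_i", "vd_i"):
            if not (getattr(self, name) > 0) or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be positive and finite")

    @property
    def ke_i(self) -> float:
        return self.cl_i / self.vd_i


@dataclass(frozen=True)
class Regimen:
    dose_per_admin: float  # mg
    tau: float  # h
    steady_state: bool = True

    def __post_init__(self):
        if self.dose_per_admin <= 0 or self.tau <= 0:
            raise ValueError("dose and interval must be positive")


def individual_parameters(
    thetas: PKThetas,
    cov: SubjectCovariates,
    eta: dict | None = None,
    dose_ref: float = DOSE_REF,
) -> PKIndividual:
    """Apply the covariate model and exponential random effects to the typicals.

    ``eta`` maps parameter names (``cl``, ``vd``, ``ka``, ``alag``) to random
    effects; missing entries default to zero.
    """
    eta = eta or {}
    dn = cov.daily_dose / dose_ref
    cl = (
        thetas.cl
        * dn**thetas.dose_exp_cl
        * thetas.factor_female ** (cov.sex == "female")
        * thetas.factor_cbz ** ("CBZ" in cov.comeds)
        * thetas.factor_clb ** ("CLB" in cov.comeds)
        * thetas.factor_pb ** ("PB" in cov.comeds)
        * thetas.factor_pht ** ("PHT" in cov.comeds)
        * math.exp(eta.get("cl", 0.0))
    )
    vd = thetas.vd * dn**thetas.dose_exp_vd * math.exp(eta.get("vd", 0.0))
    ka = thetas.ka * math.exp(eta.get("ka", 0.0))
    alag = thetas.alag * math.exp(eta.get("alag", 0.0))
    for name, value in [("cl", cl), ("vd", vd), ("ka", ka), ("alag", alag)]:
        if not math.isfinite(value):
            raise ArithmeticError(f"non-finite individual parameter {name}")
    return PKIndividual(ka_i=ka, cl_i=cl, vd_i=vd, alag_i=alag)


def _conc_arrays(t, dose, tau, ka, ke, vd, alag, steady_state):
    """Vectorised noise-free concentration; arrays broadcast elementwise.

    Extreme rate constants probed by an outer optimizer can overflow the
    exponentials; the resulting non-finite values are handled by the caller.
    """
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _conc_arrays_raw(t, dose, tau, ka, ke, vd, alag, steady_state)


def _conc_arrays_raw(t, dose, tau, ka, ke, vd, alag, steady_state):
    t = np.asarray(t, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    tied = np.abs(ka - ke) <= KA_KE_RTOL * np.maximum(np.abs(ka), np.abs(ke))
    if steady_state:
        # the steady-state profile is periodic: wrap time since dose into [0, tau)
        tp = np.mod(t - alag, tau)
        eke = np.exp(-ke * tp) / (1.0 - np.exp(-ke * tau))
        eka = np.exp(-ka * tp) / (1.0 - np.exp(-ka * tau))
        denom = np.where(tied, 1.0, ka - ke)
        general = (dose / vd) * ka / denom * (eke - eka)
        if np.any(tied):
            r = np.exp(-ke * tau)
            lim = (dose / vd) * ke * np.exp(-ke * tp) * (
                tp / (1.0 - r) + tau * r / (1.0 - r) ** 2
            )
            general = np.where(tied, lim, general)
        return general
    tp = t - alag
    pre = tp < 0
    tp = np.where(pre, 0.0, tp)
    denom = np.where(tied, 1.0, ka - ke)
    general = (dose / vd) * ka / denom * (np.exp(-ke * tp) - np.exp(-ka * tp))
    if np.any(tied):
        lim = (dose / vd) * ke * tp * np.exp(-ke * tp)
        general = np.where(tied, lim, general)
    return np.where(pre, 0.0, general)


def concentration(t, regimen: Regimen, ind: PKIndividual):
    """Noise-free concentration (mg/L) at time *t* hours after the last dose.

    Single-dose form below the lag is zero; the steady-state form superposes
    all prior doses (closed form), with the tied ka = ke limit handled
    analytically.
    """
    out = _conc_arrays(
        t, regimen.dose_per_admin, regimen.tau, ind.ka_i, ind.ke_i,
        ind.vd_i, ind.alag_i, regimen.steady_state,
    )
    if np.isscalar(t):
        return float(out)
    return out


def conc_profile(regimen: Regimen, ind: PKIndividual, n: int = 241):
    """(t, C(t)) over one dosing interval, for plotting and integration checks."""
    t = np.linspace(0.0, regimen.tau, n)
    return t, concentration(t, regimen, ind)


def auc_ss(ind: PKIndividual, daily_dose: float) -> float:
    """Steady-state 24-h area under the curve (mg*h/L) = daily dose / CL_i."""
    if ind.cl_i <= 0:
        raise ValueError("cl_i must be positive")
    return daily_dose / ind.cl_i


def with_updates(thetas: PKThetas, **kwargs) -> PKThetas:
    """Convenience: a copy of *thetas* with fields replaced."""
    return replace(thetas, **kwargs)


# ---------------------------------------------------------------------------
# population estimator

import pandas as pd  # noqa: E402
from sklearn.base import BaseEstimator  # noqa: E402

from . import mixed_effects as me  # noqa: E402

#: covariate registry: name -> ("continuous" | "categorical", builder)
#: continuous covariates enter as power terms on a log-normalised value,
#: categorical ones as multiplicative factors; cyp2c19 expands to two factors
#: (heterozygous EM and PM vs homozygous EM) and counts 2 df in selection.
AGE_REF = 18.0
WEIGHT_REF = 50.0


def _cov_columns(name: str, subjects) -> list[tuple[str, str, np.ndarray]]:
    """(term_name, kind, per-subject column) for one covariate name."""
    if name == "dose":
        x = np.log(np.array([s.daily_dose for s in subjects]) / DOSE_REF)
        return [(f"{name}", "continuous", x)]
    if name == "age":
        x = np.log(np.array([s.age for s in subjects]) / AGE_REF)
        return [(name, "continuous", x)]
    if name == "weight":
        x = np.log(np.array([s.body_weight for s in subjects]) / WEIGHT_REF)
        return [(name, "continuous", x)]
    if name == "female":
        return [(name, "categorical",
                 np.array([float(s.sex == "female") for s in subjects]))]
    if name in ("CBZ", "CLB", "PB", "PHT", "TPM", "ZNS", "GBP"):
        return [(name, "categorical",
                 np.array([float(name in s.comeds) for s in subjects]))]
    if name == "cyp2c9":
        return [("cyp2c9_star3", "categorical",
                 np.array([float(s.cyp2c9 != "*1/*1") for s in subjects]))]
    if name == "cyp2c19":
        return [
            ("cyp2c19_hetEM", "categorical",
             np.array([float(s.cyp2c19 == "hetEM") for s in subjects])),
            ("cyp2c19_PM", "categorical",
             np.array([float(s.cyp2c19 == "PM") for s in subjects])),
        ]
    raise ValueError(f"unknown covariate {name!r}")


class PopulationPKModel(BaseEstimator):
    """Population one-compartment PK estimator (FOCE with interaction).

    Parameters
    ----------
    cl_covariates, vd_covariates : tuples of covariate names
        Covariate model on CL/F and Vd/F; the defaults reproduce the final
        covariate structure (dose power, sex and co-medication factors on
        CL/F, dose power on Vd/F).
    eta_on : tuple
        Parameters carrying an estimated exponential random effect; by
        default only clearance, with the remaining variances held at the
        engine floor (their published values are effectively zero).
    residual : {"proportional", "additive"}
    alag : absorption lag in hours, fixed.

    Attributes (after fit)
    ----------------------
    theta_ (dict), omega2_ (dict), sigma2_, ofv_, converged_, ebes_
    (per-subject eta DataFrame), cl_i_ / auc_ (per-subject Series), fit_.
    """

    def __init__(
        self,
        cl_covariates: tuple = ("dose", "female", "CBZ", "CLB", "PB", "PHT"),
        vd_covariates: tuple = ("dose",),
        eta_on: tuple = ("cl",),
        residual: str = "proportional",
        alag: float = 3.0,
        dose_ref: float = DOSE_REF,
        init: dict | None = None,
        maxiter: int = 400,
        ftol: float = 1e-10,
    ):
        self.cl_covariates = cl_covariates
        self.vd_covariates = vd_covariates
        self.eta_on = eta_on
        self.residual = residual
        self.alag = alag
        self.dose_ref = dose_ref
        self.init = init
        self.maxiter = maxiter
        self.ftol = ftol

    # -- design ------------------------------------------------------------

    def _layout(self, subjects):
        names = ["ka", "cl", "vd"]
        transforms = ["log", "log", "log"]
        cols = []  # (theta_index, target, kind, per-subject values)
        for target, covs in (("cl", self.cl_covariates), ("vd", self.vd_covariates)):
            for name in covs:
                for term, kind, x in _cov_columns(name, subjects):
                    names.append(f"{target}:{term}")
                    transforms.append("identity" if kind == "continuous" else "log")
                    cols.append((len(names) - 1, target, kind, x))
        return names, transforms, cols

    def _design(self, cohort):
        subjects = sorted(cohort.subjects, key=lambda s: s.subject_id)
        ids = [s.subject_id for s in subjects]
        code = {sid: i for i, sid in enumerate(ids)}
        recs = sorted(cohort.pk_records, key=lambda r: code[r.subject_id])
        if not all(r.steady_state for r in recs):
            raise ValueError("PK estimation expects steady-state records")
        subject = np.array([code[r.subject_id] for r in recs], dtype=int)
        data = {
            "y": np.array([r.value for r in recs]),
            "subject": subject,
            "t": np.array([r.time_after_last_dose for r in recs]),
            "dose": np.array([r.dose_per_administration for r in recs]),
            "tau": np.array([r.dosing_interval for r in recs]),
        }
        daily = np.array([s.daily_dose for s in subjects])
        return data, ids, subjects, daily

    def _make_spec(self, cols, subject_cols_to_records):
        eta_on = tuple(self.eta_on)
        alag = self.alag
        rec_cols = subject_cols_to_records  # list aligned with cols: per-record arrays

        def predict(theta, eta_rec, data):
            log_cl = np.log(theta[1])
            log_vd = np.log(theta[2])
            log_ka = np.log(theta[0])
            for (j, target, kind, _), x_rec in zip(cols, rec_cols):
                term = theta[j] * x_rec if kind == "continuous" else np.log(theta[j]) * x_rec
                if target == "cl":
                    log_cl = log_cl + term
                else:
                    log_vd = log_vd + term
            for k, pname in enumerate(eta_on):
                e = eta_rec[:, k]
                if pname == "cl":
                    log_cl = log_cl + e
                elif pname == "vd":
                    log_vd = log_vd + e
                elif pname == "ka":
                    log_ka = log_ka + e
            cl = np.exp(log_cl)
            vd = np.exp(log_vd)
            ka = np.exp(log_ka)
            ke = cl / vd
            return _conc_arrays(data["t"], data["dose"], data["tau"],
                                ka, ke, vd, alag, steady_state=True)

        return me.ModelSpec(predict=predict, kind="continuous",
                            n_eta=len(eta_on), residual=self.residual)

    # -- sklearn-style API ---------------------------------------------------

    def fit(self, X, y=None):
        """Fit to a :class:`~vpapkpd.dataset.Cohort` with concentration records."""
        cohort = X
        data, ids, subjects, daily = self._design(cohort)
        names, transforms, cols = self._layout(subjects)
        rec_cols = [x[data["subject"]] for (_, _, _, x) in cols]
        spec = self._make_spec(cols, rec_cols)

        init = {"ka": 0.2, "cl": 1.0, "vd": 30.0, "omega2": 0.1, "sigma2": 0.1}
        init.update(self.init or {})
        theta0 = []
        for n, t in zip(names, transforms):
            if n in init:
                theta0.append(init[n])
            elif n in ("ka", "cl", "vd"):
                theta0.append(init[n])
            else:
                theta0.append(0.5 if t == "identity" else 1.0)
        result = me.fit(
            spec, data,
            init_theta=np.array(theta0), theta_names=names,
            theta_transforms=transforms,
            init_omega2=np.full(len(self.eta_on), init["omega2"]),
            init_sigma2=init["sigma2"],
            maxiter=self.maxiter, ftol=self.ftol,
        )
        self.fit_ = result
        self.theta_ = dict(zip(names, map(float, result.theta)))
        self.omega2_ = {p: float(v) for p, v in zip(self.eta_on, result.omega2)}
        self.sigma2_ = float(result.sigma2)
        self.ofv_ = result.ofv
        self.converged_ = result.converged
        self.subject_ids_ = ids
        self.ebes_ = pd.DataFrame(result.ebes, index=ids,
                                  columns=[f"eta_{p}" for p in self.eta_on])
        eta_cl = (self.ebes_["eta_cl"].to_numpy()
                  if "eta_cl" in self.ebes_ else np.zeros(len(ids)))
        log_cl = np.full(len(ids), np.log(self.theta_["cl"]))
        for (j, target, kind, x), _ in zip(cols, rec_cols):
            if target != "cl":
                continue
            th = result.theta[j]
            log_cl = log_cl + (th * x if kind == "continuous" else np.log(th) * x)
        self.cl_i_ = pd.Series(np.exp(log_cl + eta_cl), index=ids, name="cl_i")
        self.auc_ = pd.Series(daily / self.cl_i_.to_numpy(), index=ids, name="auc")
        self._cols = cols
        self._names = names
        return self

    def fitted_params(self) -> dict:
        d = dict(self.theta_)
        for p, v in self.omega2_.items():
            d[f"omega2_{p}"] = v
        d["sigma2"] = self.sigma2_
        return d

    def predict(self, X, individual: bool = False):
        """Noise-free predicted concentrations for a cohort's records.

        ``individual=True`` uses the empirical Bayes random effects (subjects
        unseen at fit time get eta = 0), otherwise the population prediction.
        """
        cohort = X
        data, ids, subjects, _ = self._design(cohort)
        names, transforms, cols = self._layout(subjects)
        rec_cols = [x[data["subject"]] for (_, _, _, x) in cols]
        spec = self._make_spec(cols, rec_cols)
        theta = np.array([self.theta_[n] for n in names])
        n_rec = len(data["y"])
        eta_rec = np.zeros((n_rec, len(self.eta_on)))
        if individual:
            eb = self.ebes_.reindex(ids).fillna(0.0).to_numpy()
            eta_rec = eb[data["subject"]]
        return spec.predict(theta, eta_rec, data)

    def ofv(self, X) -> float:
        """OFV of the fitted parameters on a (possibly new) cohort."""
        cohort = X
        data, ids, subjects, _ = self._design(cohort)
        names, transforms, cols = self._layout(subjects)
        rec_cols = [x[data["subject"]] for (_, _, _, x) in cols]
        spec = self._make_spec(cols, rec_cols)
        theta = np.array([self.theta_[n] for n in names])
        omega2 = np.array([self.omega2_[p] for p in self.eta_on])
        return me.marginal_nll(spec, data, theta, omega2, self.sigma2_)
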