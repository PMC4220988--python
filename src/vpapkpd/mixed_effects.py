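"""Marginal-likelihood machinery for nonlinear mixed-effects models.

The engine handles two observation types through one interface:

* continuous observations with a proportional (or additive) residual error
  model, marginalised by first-order conditional estimation with interaction
  (FOCE-I): the model is linearised in the random effect around each subject's
  empirical Bayes mode and the resulting Gaussian marginal evaluated exactly;
* binary observations, marginalised by the Laplace approximation (second-order
  expansion of the joint log-density at the mode); adaptive Gauss-Hermite
  quadrature is available both as a high-accuracy alternative and as an
  independent cross-check.

The objective function value (OFV) is -2 log marginal likelihood including
the 2*pi constants, so Laplace/FOCE values are directly comparable with the
quadrature and closed-form Gaussian references.  Only OFV *differences*
between nested models are interpreted inferentially.

Random effects are assumed independent across subjects with diagonal
covariance omega^2; the per-subject inner problem (finding the posterior mode
of eta) is solved by a damped Newton iteration, vectorised across subjects
for the common one-dimensional case.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize

__all__ = [
    "ModelSpec",
    "ModelFit",
    "inner_mode",
    "marginal_nll",
    "agq_nll",
    "fit",
    "OMEGA2_FLOOR",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: lower floor for omega^2 during estimation; effectively-zero random effects
#: are held at this value to avoid singular curvature
OMEGA2_FLOOR = 1e-10

_PRED_FLOOR = 1e-12  # floor on predictions/probabilities inside likelihoods
_PROB_CLAMP = 1e-12


@dataclass
class ModelSpec:
    """A prediction function plus enough structure to marginalise it.

    ``predict(theta, eta_rec, data)`` maps the natural-scale fixed effects,
    a per-record array of random effects (n_records, n_eta) and the data
    dictionary to a per-record prediction: the mean for continuous data, the
    event probability for binary data.  It must be deterministic.

    ``data`` must contain ``y`` (observations) and ``subject`` (int codes,
    sorted ascending, one block per subject); any other arrays the prediction
    needs travel in the same dictionary.
    """

    predict: Callable[[np.ndarray, np.ndarray, Mapping], np.ndarray]
    kind: str = "continuous"  # or "binary"
    n_eta: int = 1
    residual: str = "proportional"  # continuous only: proportional | additive

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError("kind must be 'continuous' or 'binary'")
        if self.residual not in ("proportional", "additive"):
            raise ValueError("residual must be 'proportional' or 'additive'")


@dataclass
class ModelFit:
    theta: np.ndarray
    theta_names: list
    omega2: np.ndarray
    sigma2: float | None
    ofv: float
    converged: bool
    ebes: np.ndarray  # (n_subjects, n_eta)
    n_inner_failures: int = 0
    n_subjects: int = 0
    message: str = ""
    se: np.ndarray | None = None

    def params(self) -> dict:
        d = dict(zip(self.theta_names, (float(v) for v in self.theta)))
        for k, v in enumerate(np.atleast_1d(self.omega2)):
            d[f"omega2_{k}"] = float(v)
        if self.sigma2 is not None:
            d["sigma2"] = float(self.sigma2)
        return d


def _group_starts(subject: np.ndarray) -> tuple[np.ndarray, int]:
    subject = np.asarray(subject)
    if subject.size and np.any(np.diff(subject) < 0):
        raise ValueError("records must be sorted by subject code")
    n_sub = int(subject.max()) + 1 if subject.size else 0
    starts = np.searchsorted(subject, np.arange(n_sub))
    return starts, n_sub


def _record_m2ll(spec: ModelSpec, theta, eta_rec, data, sigma2):
    """-2 log p(y | eta) per record."""
    y = data["y"]
    pred = spec.predict(theta, eta_rec, data)
    if spec.kind == "binary":
        p = np.clip(pred, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
        return -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))
    f = pred
    if spec.residual == "proportional":
        var = sigma2 * np.maximum(f * f, _PRED_FLOOR)
    else:
        var = np.full_like(f, sigma2)
    return np.log(2.0 * np.pi * var) + (y - f) ** 2 / var


def _subject_m2ll(spec, theta, eta_sub, data, omega2, sigma2, starts):
    """-2 log joint density per subject, prior included.

    ``starts`` carries the number of subjects; groupwise sums use bincount so
    subjects without observations contribute only their prior term.
    """
    n_sub = len(starts)
    eta_rec = eta_sub[data["subject"]]
    terms = _record_m2ll(spec, theta, eta_rec, data, sigma2)
    g = np.bincount(data["subject"], weights=terms, minlength=n_sub)
    prior = np.sum(np.log(2.0 * np.pi * omega2) + eta_sub**2 / omega2, axis=-1)
    return g + prior


def inner_mode(
    spec: ModelSpec,
    data: Mapping,
    theta: np.ndarray,
    omega2: np.ndarray,
    sigma2: float | None = None,
    eta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
):
    """Empirical Bayes modes and curvatures for every subject.

    Returns ``(eta_hat, hess, flags)`` where ``hess`` is the second derivative
    of the per-subject -2 log joint density at the mode (per eta dimension for
    the vectorised 1-d path, full matrices otherwise) and ``flags`` marks
    subjects whose Newton iteration did not converge.

    A subject with no observations has its mode at the prior mean (zero); as
    omega^2 -> 0 the prior dominates and the mode collapses to zero.
    """
    omega2 = np.atleast_1d(np.asarray(omega2, dtype=float))
    if np.any(omega2 <= 0):
        raise ValueError("omega2 entries must be positive (floor tiny ones)")
    subject = np.asarray(data["subject"])
    starts, n_sub = _group_starts(subject)
    d = spec.n_eta
    if d != omega2.size:
        raise ValueError("omega2 length must equal spec.n_eta")
    if d == 1:
        return _inner_mode_1d(spec, data, theta, omega2, sigma2, eta0, tol,
                              max_iter, starts, n_sub)
    return _inner_mode_nd(spec, data, theta, omega2, sigma2, eta0, tol,
                          max_iter, starts, n_sub)


def _inner_mode_1d(spec, data, theta, omega2, sigma2, eta0, tol, max_iter,
                   starts, n_sub):
    h = 1e-5
    eta = np.zeros((n_sub, 1)) if eta0 is None else np.array(eta0, dtype=float).reshape(n_sub, 1)

    def g_of(e):
        return _subject_m2ll(spec, theta, e.reshape(-1, 1), data, omega2, sigma2, starts)

    g0 = g_of(eta[:, 0])
    converged = np.zeros(n_sub, dtype=bool)
    for _ in range(max_iter):
        e = eta[:, 0]
        gp = g_of(e + h)
        gm = g_of(e - h)
        g1 = (gp - gm) / (2 * h)
        g2 = (gp - 2 * g0 + gm) / (h * h)
        g2 = np.maximum(g2, 1e-3 / omega2[0])  # guard non-convex stretches
        step = -g1 / g2
        step = np.clip(step, -3.0, 3.0)
        newly = np.abs(step) < tol
        converged |= newly
        active = ~converged
        if not np.any(active):
            break
        # damped update: halve the step while the objective worsens
        trial = e + np.where(active, step, 0.0)
        for _ in range(25):
            g_trial = g_of(trial)
            worse = active & (g_trial > g0 + 1e-12)
            if not np.any(worse):
                break
            trial = np.where(worse, (trial + e) / 2.0, trial)
        improved = active & (g_trial <= g0 + 1e-12)
        e = np.where(improved, trial, e)
        g0 = np.where(improved, g_trial, g0)
        eta[:, 0] = e
        converged |= active & ~improved & (np.abs(g1) < 1e-6)
    e = eta[:, 0]
    gp = g_of(e + h)
    gm = g_of(e - h)
    g0 = g_of(e)
    g1 = (gp - gm) / (2 * h)
    g2 = np.maximum((gp - 2 * g0 + gm) / (h * h), 1e-3 / omega2[0])
    # a subject fails only if the stationarity condition is materially violated
    flags = np.abs(g1) > 1e-3 * np.maximum(1.0, np.abs(g0))
    return eta, g2.reshape(-1, 1, 1), flags


def _inner_mode_nd(spec, data, theta, omega2, sigma2, eta0, tol, max_iter,
                   starts, n_sub):
    d = spec.n_eta
    subject = np.asarray(data["subject"])
    eta = np.zeros((n_sub, d)) if eta0 is None else np.array(eta0, dtype=float)
    hess = np.zeros((n_sub, d, d))
    flags = np.zeros(n_sub, dtype=bool)
    scale = np.sqrt(omega2)  # optimise in prior-standardised coordinates

    for i in range(n_sub):
        mask = subject == i
        sub_data = {k: (v[mask] if isinstance(v, np.ndarray) and v.shape[:1] == subject.shape else v)
                    for k, v in data.items()}
        sub_data["subject"] = np.zeros(int(mask.sum()), dtype=int)
        sub_starts = np.array([0])

        def g_of(z):
            return _subject_m2ll(spec, theta, (scale * z).reshape(1, d), sub_data,
                                 omega2, sigma2, sub_starts)[0]

        res = optimize.minimize(g_of, eta[i] / scale, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 200})
        z_hat = res.x
        eta[i] = scale * z_hat
        flags[i] = not res.success and np.linalg.norm(res.jac) > 1e-4
        # central-difference Hessian of the -2 log joint (standardised coords)
        h = 1e-4
        H = np.zeros((d, d))
        g0 = g_of(z_hat)
        for a in range(d):
            for b in range(a, d):
                ea = np.zeros(d); ea[a] = h
                eb = np.zeros(d); eb[b] = h
                if a == b:
                    H[a, a] = (g_of(z_hat + ea) - 2 * g0 + g_of(z_hat - ea)) / h**2
                else:
                    H[a, b] = H[b, a] = (
                        g_of(z_hat + ea + eb) - g_of(z_hat + ea - eb)
                        - g_of(z_hat - ea + eb) + g_of(z_hat - ea - eb)
                    ) / (4 * h**2)
        # ridge-adjust non-positive-definite curvature
        w = np.linalg.eigvalsh(H)
        if w.min() <= 0:
            H = H + (abs(w.min()) + 1e-6) * np.eye(d)
            flags[i] = True
        hess[i] = H / np.outer(scale, scale)  # back to eta coordinates
    return eta, hess, flags


def marginal_nll(
    spec: ModelSpec,
    data: Mapping,
    theta: np.ndarray,
    omega2: np.ndarray,
    sigma2: float | None = None,
    eta_hat: np.ndarray | None = None,
    method: str | None = None,
    per_subject: bool = False,
):
    """-2 log marginal likelihood (OFV), summed over subjects.

    ``method`` defaults to FOCE-I for continuous data and Laplace for binary
    data; ``"laplace"`` and ``"agq"`` are accepted for either kind.
    """
    omega2 = np.atleast_1d(np.asarray(omega2, dtype=float))
    if method is None:
        method = "foce" if spec.kind == "continuous" else "laplace"
    if method == "agq":
        out, flags = agq_nll(spec, data, theta, omega2, sigma2, per_subject=True), None
        return (out if per_subject else float(np.sum(out)))
    eta_hat, hess, flags = inner_mode(spec, data, theta, omega2, sigma2, eta0=eta_hat)
    starts, n_sub = _group_starts(data["subject"])
    if method == "foce" and spec.kind == "continuous" and spec.n_eta == 1:
        out = _foce_m2ll_1d(spec, data, theta, omega2, sigma2, eta_hat, starts)
    elif method in ("laplace", "foce"):
        out = _laplace_m2ll(spec, data, theta, omega2, sigma2, eta_hat, hess, starts)
    else:
        raise ValueError(f"unknown method {method!r}")
    if per_subject:
        return out
    return float(np.sum(out))


def _laplace_m2ll(spec, data, theta, omega2, sigma2, eta_hat, hess, starts):
    g = _subject_m2ll(spec, theta, eta_hat, data, omega2, sigma2, starts)
    d = spec.n_eta
    if hess.shape[1:] == (1, 1):
        logdet = np.log(hess[:, 0, 0] / 2.0)
    else:
        sign, logabs = np.linalg.slogdet(hess / 2.0)
        logdet = logabs
    return g + logdet - d * LOG2PI


def _foce_m2ll_1d(spec, data, theta, omega2, sigma2, eta_hat, starts):
    """FOCE with interaction for a scalar random effect (rank-1 marginal covariance)."""
    subject = data["subject"]
    y = data["y"]
    eta_rec = eta_hat[subject]
    h = 1e-5
    F = spec.predict(theta, eta_rec, data)
    Gp = spec.predict(theta, eta_rec + h, data)
    Gm = spec.predict(theta, eta_rec - h, data)
    G = (Gp - Gm) / (2 * h)
    if spec.residual == "proportional":
        dvar = sigma2 * np.maximum(F * F, _PRED_FLOOR)
    else:
        dvar = np.full_like(F, sigma2)
    r = y - F + G * eta_hat[subject, 0]
    w2 = float(omega2[0])
    n_sub = len(starts)
    s_gg = np.bincount(subject, weights=G * G / dvar, minlength=n_sub)
    s_gr = np.bincount(subject, weights=G * r / dvar, minlength=n_sub)
    s_rr = np.bincount(subject, weights=r * r / dvar, minlength=n_sub)
    s_logd = np.bincount(subject, weights=np.log(2.0 * np.pi * dvar), minlength=n_sub)
    c = 1.0 + w2 * s_gg
    return s_logd + np.log(c) + s_rr - w2 * s_gr**2 / c


def agq_nll(
    spec: ModelSpec,
    data: Mapping,
    theta: np.ndarray,
    omega2: np.ndarray,
    sigma2: float | None = None,
    n_nodes: int = 64,
    per_subject: bool = False,
    eta0: np.ndarray | None = None,
    modes: tuple | None = None,
):
    """Adaptive Gauss-Hermite -2 log marginal likelihood (scalar eta only).

    The quadrature is centred at each subject's posterior mode and scaled by
    the local curvature; 64 nodes give near-exact one-dimensional integrals
    and serve as the engine's accuracy reference.  ``modes`` may carry
    precomputed ``(eta_hat, hess)`` to reuse an inner solve.
    """
    omega2 = np.atleast_1d(np.asarray(omega2, dtype=float))
    if spec.n_eta != 1:
        raise NotImplementedError("quadrature reference implemented for one eta")
    if modes is not None:
        eta_hat, hess = modes
    else:
        eta_hat, hess, _ = inner_mode(spec, data, theta, omega2, sigma2, eta0=eta0)
    starts, n_sub = _group_starts(data["subject"])
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    scale = np.sqrt(2.0 / hess[:, 0, 0])  # = sqrt(2) * (H/2)^{-1/2}
    # nodes: (n_sub, n_nodes)
    nodes = eta_hat[:, 0:1] + scale[:, None] * x[None, :]
    logdens = np.empty((n_sub, n_nodes))
    for k in range(n_nodes):
        g = _subject_m2ll(spec, theta, nodes[:, k:k+1], data, omega2, sigma2, starts)
        logdens[:, k] = -0.5 * g  # log joint density
    # log sum_k w_k exp(x_k^2) * joint(node_k) * scale
    logw = np.log(w)[None, :] + x[None, :] ** 2 + logdens
    m = logw.max(axis=1)
    logL = m + np.log(np.sum(np.exp(logw - m[:, None]), axis=1)) + np.log(scale)
    out = -2.0 * logL
    if per_subject:
        return out
    return float(np.sum(out))


# ---------------------------------------------------------------------------
# outer estimation


@dataclass
class _ParamSpec:
    """Packing/unpacking of natural parameters to the unconstrained scale."""

    names: list
    transforms: list  # "log" | "identity" per theta
    n_eta: int
    estimate_sigma2: bool
    fixed_omega2: np.ndarray | None = None  # entries not estimated (NaN = estimated)

    def pack(self, theta, omega2, sigma2):
        x = [np.log(v) if t == "log" else v for v, t in zip(theta, self.transforms)]
        for j in range(self.n_eta):
            if self.fixed_omega2 is None or np.isnan(self.fixed_omega2[j]):
                x.append(np.log(max(omega2[j], OMEGA2_FLOOR)))
        if self.estimate_sigma2:
            x.append(np.log(sigma2))
        return np.asarray(x, dtype=float)

    def bounds(self):
        """Loose box bounds keeping the optimizer out of overflow regions."""
        out = []
        for t in self.transforms:
            out.append((np.log(1e-4), np.log(1e4)) if t == "log" else (-60.0, 60.0))
        n_var = sum(
            1 for j in range(self.n_eta)
            if self.fixed_omega2 is None or np.isnan(self.fixed_omega2[j])
        )
        out.extend([(np.log(OMEGA2_FLOOR), np.log(1e4))] * n_var)
        if self.estimate_sigma2:
            out.append((np.log(1e-10), np.log(1e4)))
        return out

    def unpack(self, x):
        k = len(self.transforms)
        theta = np.array(
            [np.exp(v) if t == "log" else v for v, t in zip(x[:k], self.transforms)]
        )
        omega2 = np.empty(self.n_eta)
        i = k
        for j in range(self.n_eta):
            if self.fixed_omega2 is None or np.isnan(self.fixed_omega2[j]):
                omega2[j] = max(np.exp(x[i]), OMEGA2_FLOOR)
                i += 1
            else:
                omega2[j] = max(self.fixed_omega2[j], OMEGA2_FLOOR)
        sigma2 = float(np.exp(x[i])) if self.estimate_sigma2 else None
        return theta, omega2, sigma2


def fit(
    spec: ModelSpec,
    data: Mapping,
    init_theta: np.ndarray,
    theta_names: list,
    theta_transforms: list,
    init_omega2: np.ndarray,
    init_sigma2: float | None = None,
    fixed_omega2: np.ndarray | None = None,
    method: str | None = None,
    maxiter: int = 400,
    ftol: float = 1e-10,
    inner_failure_limit: float = 0.05,
    compute_se: bool = False,
    agq_nodes: int = 25,
) -> ModelFit:
    """Maximise the marginal likelihood over the population parameters.

    Positivity is enforced by log transforms declared per parameter; omega^2
    and sigma^2 are always estimated on the log scale.  Entries of
    ``fixed_omega2`` that are not NaN are held fixed (floored).  The inner
    empirical Bayes problem is warm-started across outer iterations.  A fit
    with more than ``inner_failure_limit`` flagged subjects is reported as
    non-converged, mirroring the "successful minimisation" notion used when
    screening bootstrap replicates.
    """
    init_theta = np.asarray(init_theta, dtype=float)
    init_omega2 = np.maximum(np.atleast_1d(np.asarray(init_omega2, dtype=float)),
                             OMEGA2_FLOOR)
    pspec = _ParamSpec(
        names=list(theta_names),
        transforms=list(theta_transforms),
        n_eta=spec.n_eta,
        estimate_sigma2=init_sigma2 is not None,
        fixed_omega2=fixed_omega2,
    )
    x0 = pspec.pack(init_theta, init_omega2, init_sigma2)
    starts, n_sub = _group_starts(data["subject"])
    state = {"eta": np.zeros((n_sub, spec.n_eta)), "flags": 0}
    # per-observation scaling keeps the unit-Hessian first L-BFGS-B step at
    # a sensible length and the line search inside the finite region
    scale = float(max(1, len(np.asarray(data["y"]))))
    BAD = 1e9

    if method is None:
        method = "foce" if spec.kind == "continuous" else "laplace"

    def objective(x):
        theta, omega2, sigma2 = pspec.unpack(x)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                eta_hat, hess, flags = inner_mode(
                    spec, data, theta, omega2, sigma2, eta0=state["eta"]
                )
            except (FloatingPointError, ValueError):
                return BAD / scale
            if not np.all(np.isfinite(eta_hat)):
                return BAD / scale
            if method == "foce" and spec.kind == "continuous" and spec.n_eta == 1:
                out = _foce_m2ll_1d(spec, data, theta, omega2, sigma2, eta_hat, starts)
            elif method == "agq":
                out = agq_nll(spec, data, theta, omega2, sigma2,
                              n_nodes=agq_nodes, per_subject=True,
                              modes=(eta_hat, hess))
            else:
                out = _laplace_m2ll(spec, data, theta, omega2, sigma2, eta_hat, hess, starts)
        total = float(np.sum(out))
        if not np.isfinite(total) or total >= BAD:
            # do not poison the warm start with modes from a degenerate point
            return BAD / scale
        state["eta"] = np.clip(eta_hat, -30.0, 30.0)
        state["flags"] = int(flags.sum())
        return total / scale

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=pspec.bounds(),
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-7, "eps": 1e-5},
    )
    theta, omega2, sigma2 = pspec.unpack(res.x)
    ofv = objective(res.x) * scale  # refresh state at the optimum
    n_failures = state["flags"]
    converged = bool(res.success) and (n_failures <= inner_failure_limit * max(n_sub, 1))
    se = None
    if compute_se:
        se = _outer_se(lambda x: objective(x) * scale, res.x, pspec)
    return ModelFit(
        theta=theta, theta_names=list(theta_names), omega2=omega2, sigma2=sigma2,
        ofv=float(ofv), converged=converged, ebes=state["eta"].copy(),
        n_inner_failures=n_failures, n_subjects=n_sub, message=str(res.message), se=se,
    )


def _outer_se(objective, x_opt, pspec):
    """Asymptotic SEs of theta from a central-difference Hessian of the OFV.

    The OFV is -2 log L, so the covariance is 2 * H^{-1}; the delta method
    maps log-scale variances back to the natural scale.
    """
    n = len(x_opt)
    h = 1e-4
    H = np.zeros((n, n))
    f0 = objective(x_opt)
    for a in range(n):
        for b in range(a, n):
            ea = np.zeros(n); ea[a] = h
            eb = np.zeros(n); eb[b] = h
            if a == b:
                H[a, a] = (objective(x_opt + ea) - 2 * f0 + objective(x_opt - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    objective(x_opt + ea + eb) - objective(x_opt + ea - eb)
                    - objective(x_opt - ea + eb) + objective(x_opt - ea - eb)
                ) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.clip(np.diag(cov), 0.0, np.inf)
    k = len(pspec.transforms)
    theta, _, _ = pspec.unpack(x_opt)
    se = np.sqrt(var[:k])
    for j, t in enumerate(pspec.transforms):
        if t == "log":
            se[j] = theta[j] * se[j]  # delta method for exp
    return se
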