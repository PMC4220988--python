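"""Model validation: stratified bootstrap, visual predictive check, GOF.

* ``bootstrap`` resamples whole subjects with replacement, preserving the
  per-stratum subject counts, refits the estimator on every replicate, and
  summarises the successful replicates by their median and 2.5/97.5
  percentiles per parameter.
* ``vpc`` simulates replicate outcome sets from a fitted exposure-response
  model at the observed design and compares observed proportions of gamma-GT
  elevation per stratum and exposure bin with the 5th-95th percentile band
  (90% prediction interval) of the simulated proportions.
* ``gof_diagnostics`` returns population and individual (empirical Bayes)
  predictions and conditional weighted residuals for a fitted PK model.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .dataset import Cohort

__all__ = ["BootstrapResult", "bootstrap", "vpc", "gof_diagnostics"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    n_requested: int
    n_successful: int
    summary: pd.DataFrame  # index: parameter; columns: median, ci_low, ci_high
    estimates: pd.DataFrame  # one row per successful replicate
    unreliable: bool = False

    def __post_init__(self):
        if self.n_successful > self.n_requested:
            raise ValueError("n_successful cannot exceed n_requested")


def _resample_cohort(cohort: Cohort, rng, strata: dict | None) -> Cohort:
    """Subject-level resampling with replacement, per-stratum sizes preserved."""
    ids = [s.subject_id for s in cohort.subjects]
    if strata is None:
        groups = {None: ids}
    else:
        groups = {}
        for sid in ids:
            groups.setdefault(strata[sid], []).append(sid)
    chosen = []
    for label in sorted(groups, key=str):
        members = groups[label]
        chosen.extend(rng.choice(members, size=len(members), replace=True))
    by_id = {s.subject_id: s for s in cohort.subjects}
    pk_by_id: dict[str, list] = {}
    for r in cohort.pk_records:
        pk_by_id.setdefault(r.subject_id, []).append(r)
    ggt_by_id: dict[str, list] = {}
    for r in cohort.ggt_records:
        ggt_by_id.setdefault(r.subject_id, []).append(r)
    subjects, pk_records, ggt_records = [], [], []
    for k, sid in enumerate(chosen):
        new_id = f"B{k:04d}_{sid}"
        subjects.append(dataclasses.replace(by_id[sid], subject_id=new_id))
        for r in pk_by_id.get(sid, []):
            pk_records.append(dataclasses.replace(r, subject_id=new_id))
        for r in ggt_by_id.get(sid, []):
            ggt_records.append(dataclasses.replace(r, subject_id=new_id))
    return Cohort(subjects, pk_records, ggt_records)


def _resample_table(table: pd.DataFrame, rng, strata: dict | None) -> pd.DataFrame:
    ids = list(pd.unique(table["subject_id"]))
    if strata is None:
        groups = {None: ids}
    else:
        groups = {}
        for sid in ids:
            groups.setdefault(strata[sid], []).append(sid)
    chosen = []
    for label in sorted(groups, key=str):
        members = groups[label]
        chosen.extend(rng.choice(members, size=len(members), replace=True))
    parts = []
    for k, sid in enumerate(chosen):
        part = table[table["subject_id"] == sid].copy()
        part["subject_id"] = f"B{k:04d}_{sid}"
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def bootstrap(
    data,
    estimator,
    n: int = 1000,
    strata: dict | None = None,
    seed=None,
    extra_params: tuple = (),
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of a fitted estimator.

    ``data`` is a :class:`Cohort` (PK estimator) or a tidy observation table
    (PD estimator); ``strata`` maps subject_id to a stratum label.  Replicates
    whose refit does not reach successful minimisation are excluded from the
    percentile summaries; the result is flagged unreliable when fewer than
    half succeed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_success = 0
    for _ in range(n):
        sample = (
            _resample_cohort(data, rng, strata)
            if isinstance(data, Cohort)
            else _resample_table(data, rng, strata)
        )
        try:
            fitted = clone(estimator).fit(sample)
        except (ValueError, ArithmeticError) as exc:
            logger.warning("bootstrap replicate raised %s; excluded", exc)
            continue
        if not fitted.converged_:
            continue
        n_success += 1
        rows.append(fitted.fitted_params())
    estimates = pd.DataFrame(rows)
    if len(estimates):
        summary = pd.DataFrame(
            {
                "median": estimates.median(),
                "ci_low": estimates.quantile(0.025),
                "ci_high": estimates.quantile(0.975),
            }
        )
    else:
        summary = pd.DataFrame(columns=["median", "ci_low", "ci_high"])
    return BootstrapResult(
        n_requested=n,
        n_successful=n_success,
        summary=summary,
        estimates=estimates,
        unreliable=n_success < 0.5 * n,
    )


def vpc(
    table: pd.DataFrame,
    model,
    n_sim: int = 1000,
    strata: tuple = (),
    n_bins: int = 4,
    seed=None,
    band: tuple = (5.0, 95.0),
) -> pd.DataFrame:
    """Visual predictive check for the binary gamma-GT endpoint.

    Observations are grouped by the categorical columns in ``strata`` and by
    quantile bins of exposure (the ``auc`` column) within each stratum; for
    each cell the observed proportion elevated is compared with the 90%
    prediction interval of proportions across ``n_sim`` simulated replicates
    (new random intercepts and Bernoulli outcomes at the observed design).
    Empty bins are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True).copy()
    omega = float(np.sqrt(model.omega2_))
    codes, uniques = pd.factorize(table["subject_id"], sort=True)
    logit0 = model.predict_logit(table)  # eta = 0 component

    # bin assignment: quantile bins of AUC within each stratum
    if strata:
        group_key = table[list(strata)].astype(str).agg("|".join, axis=1)
    else:
        group_key = pd.Series(["all"] * len(table))
    bin_label = pd.Series(index=table.index, dtype=object)
    for g in group_key.unique():
        mask = group_key == g
        vals = table.loc[mask, "auc"]
        k = min(n_bins, max(1, vals.nunique()))
        try:
            bins = pd.qcut(vals, q=k, duplicates="drop")
        except ValueError:
            bins = pd.Series(["(all)"] * mask.sum(), index=vals.index)
        bin_label.loc[mask] = bins.astype(str)
    cell = group_key + " / " + bin_label.astype(str)

    y = table["elevated"].to_numpy(dtype=float)
    cells = pd.unique(cell)
    masks = {c: (cell == c).to_numpy() for c in cells}
    obs = {c: float(y[m].mean()) if m.sum() else np.nan for c, m in masks.items()}

    sim_props = {c: np.empty(n_sim) for c in cells}
    n_sub = len(uniques)
    for s in range(n_sim):
        eta = rng.normal(0.0, omega, size=n_sub)[codes]
        p = 1.0 / (1.0 + np.exp(-(logit0 + eta)))
        ysim = rng.random(len(p)) < p
        for c, m in masks.items():
            sim_props[c][s] = ysim[m].mean()
    rows = []
    for c in cells:
        m = masks[c]
        if not m.sum():
            logger.warning("VPC bin %s is empty; dropped", c)
            continue
        lo, hi = np.percentile(sim_props[c], band)
        stratum, _, bin_part = c.partition(" / ")
        rows.append(
            {
                "stratum": stratum, "bin": bin_part, "n_obs": int(m.sum()),
                "observed": obs[c], "pi_low": float(lo), "pi_high": float(hi),
                "inside": bool(lo <= obs[c] <= hi),
            }
        )
    return pd.DataFrame(rows)


def gof_diagnostics(cohort: Cohort, pk_model) -> pd.DataFrame:
    """Goodness-of-fit table for a fitted population PK model.

    Per record: the population prediction (eta = 0), the individual
    empirical Bayes prediction, and the conditional weighted residual from
    the FOCE-with-interaction linearisation
    ``CWRES = V^{-1/2} (y - F + G eta_hat)`` with
    ``V = diag(residual var) + omega^2 G G'`` per subject.
    """
    from . import mixed_effects as me

    data, ids, subjects, _ = pk_model._design(cohort)
    names, transforms, cols = pk_model._layout(subjects)
    rec_cols = [x[data["subject"]] for (_, _, _, x) in cols]
    spec = pk_model._make_spec(cols, rec_cols)
    theta = np.array([pk_model.theta_[n] for n in names])
    omega2 = np.array([pk_model.omega2_[p] for p in pk_model.eta_on])
    sigma2 = pk_model.sigma2_
    subject = data["subject"]
    y = data["y"]
    n_rec = len(y)

    eta_hat, hess, flags = me.inner_mode(spec, data, theta, omega2, sigma2)
    zeros = np.zeros((n_rec, spec.n_eta))
    pred_pop = spec.predict(theta, zeros, data)
    eta_rec = eta_hat[subject]
    pred_ind = spec.predict(theta, eta_rec, data)

    h = 1e-5
    F = pred_ind
    G = (spec.predict(theta, eta_rec + h, data) - spec.predict(theta, eta_rec - h, data)) / (2 * h)
    if spec.residual == "proportional":
        dvar = sigma2 * np.maximum(F * F, 1e-12)
    else:
        dvar = np.full_like(F, sigma2)
    r = y - F + G * eta_hat[subject, 0]
    w2 = float(omega2[0])
    cwres = np.empty(n_rec)
    for i in range(len(ids)):
        m = subject == i
        if not m.any():
            continue
        V = np.diag(dvar[m]) + w2 * np.outer(G[m], G[m])
        try:
            L = np.linalg.cholesky(V)
            cwres[m] = np.linalg.solve(L, r[m])
        except np.linalg.LinAlgError:
            cwres[m] = r[m] / np.sqrt(dvar[m])  # fall back to plain WRES
    return pd.DataFrame(
        {
            "subject_id": [ids[i] for i in subject],
            "observed": y,
            "pred_population": pred_pop,
            "pred_individual": pred_ind,
            "cwres": cwres,
        }
    )
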