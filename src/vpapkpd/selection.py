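"""Stepwise covariate model building on objective-function changes.

Forward inclusion adds, at each step, the candidate whose inclusion lowers
the OFV most, provided the drop reaches the chi-square significance
threshold for its degrees of freedom (3.84 for 1 df, 5.99 for 2 df at
P < 0.05); backward elimination then removes, one at a time, the retained
covariate whose removal raises the OFV least, while that rise stays below
the same threshold.  Ties are broken by candidate list order, and candidate
fits that fail to converge are skipped with a logged warning.

Candidates are applied by cloning the estimator with a modified covariate
tuple (sklearn ``get_params``/``set_params``), so the same machinery drives
both the PK model (multiplicative/power covariates on CL/F and Vd/F) and
the PD model (additive logit covariates on the intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from sklearn.base import clone

__all__ = [
    "CandidateCovariate",
    "default_thresholds",
    "forward_inclusion",
    "backward_elimination",
]

logger = logging.getLogger(__name__)


def default_thresholds(alpha: float = 0.05) -> dict:
    """Chi-square upper-alpha critical values by degrees of freedom."""
    return {df: float(stats.chi2.ppf(1.0 - alpha, df)) for df in (1, 2)}


@dataclass(frozen=True)
class CandidateCovariate:
    """One candidate term: a covariate name added to an estimator parameter.

    ``param`` names the estimator's covariate-tuple parameter (for example
    ``cl_covariates`` on the PK model or ``covariates`` on the PD model);
    ``df`` is the degrees of freedom the term consumes (2 for three-level
    categorical covariates coded as two indicators).
    """

    name: str
    param: str = "covariates"
    df: int = 1

    def __post_init__(self):
        if self.df not in (1, 2):
            raise ValueError("df must be 1 or 2")


def _with_candidates(estimator, active: tuple) -> object:
    new = clone(estimator)
    params = new.get_params()
    by_param: dict[str, list] = {}
    for cand in active:
        by_param.setdefault(cand.param, []).append(cand.name)
    for param, names in by_param.items():
        current = list(params[param])
        for n in names:
            if n not in current:
                current.append(n)
        new.set_params(**{param: tuple(current)})
    return new


def _without_candidate(estimator, base_estimator, active: tuple):
    return _with_candidates(base_estimator, active)


def _try_fit(estimator, X):
    try:
        fitted = estimator.fit(X)
    except (ValueError, ArithmeticError) as exc:
        logger.warning("candidate fit raised %s; skipped", exc)
        return None
    if not fitted.converged_:
        logger.warning("candidate fit did not converge; skipped")
        return None
    return fitted


def forward_inclusion(
    estimator,
    X,
    candidates,
    thresholds: dict | None = None,
):
    """Greedy forward inclusion from the (fitted or unfitted) base estimator.

    Returns ``(fitted_full_model, trace)`` where the trace is a DataFrame of
    every candidate evaluation (step, candidate, OFVs, delta, decision).
    """
    thresholds = thresholds or default_thresholds()
    base = _try_fit(clone(estimator), X)
    if base is None:
        raise RuntimeError("base model did not converge; cannot select covariates")
    included: list[CandidateCovariate] = []
    remaining = list(candidates)
    rows = []
    step = 0
    current = base
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            trial = _try_fit(_with_candidates(estimator, tuple(included) + (cand,)), X)
            if trial is None:
                rows.append((step, cand.name, current.ofv_, float("nan"),
                             float("nan"), "skipped (non-convergent)"))
                continue
            delta = current.ofv_ - trial.ofv_
            rows.append((step, cand.name, current.ofv_, trial.ofv_, delta, ""))
            significant = delta >= thresholds[cand.df]
            if significant and (best is None or delta > best[0]):
                best = (delta, cand, trial)
        if best is None:
            break
        delta, cand, trial = best
        rows.append((step, cand.name, current.ofv_, trial.ofv_, delta, "included"))
        included.append(cand)
        remaining.remove(cand)
        current = trial
    trace = pd.DataFrame(
        rows, columns=["step", "candidate", "ofv_base", "ofv_candidate",
                       "delta_ofv", "decision"],
    )
    current.included_candidates_ = tuple(included)
    return current, trace


def backward_elimination(
    estimator,
    X,
    removable,
    thresholds: dict | None = None,
):
    """Backward elimination of *removable* candidates from the full model.

    ``estimator`` describes the base (pre-forward) model; the full model is
    base + all removable candidates.  At each step the candidate whose
    removal raises the OFV least is dropped if that rise is below its
    threshold; elimination stops when every remaining removal is significant.
    Returns ``(fitted_final_model, trace)``.
    """
    thresholds = thresholds or default_thresholds()
    retained = list(removable)
    current = _try_fit(_with_candidates(estimator, tuple(retained)), X)
    if current is None:
        raise RuntimeError("full model did not converge; cannot eliminate covariates")
    rows = []
    step = 0
    while retained:
        step += 1
        best = None
        for cand in retained:
            reduced_set = tuple(c for c in retained if c is not cand)
            trial = _try_fit(_with_candidates(estimator, reduced_set), X)
            if trial is None:
                rows.append((step, cand.name, current.ofv_, float("nan"),
                             float("nan"), "skipped (non-convergent)"))
                continue
            delta = trial.ofv_ - current.ofv_  # rise caused by removal
            rows.append((step, cand.name, current.ofv_, trial.ofv_, delta, ""))
            removable_now = delta < thresholds[cand.df]
            if removable_now and (best is None or delta < best[0]):
                best = (delta, cand, trial)
        if best is None:
            break
        delta, cand, trial = best
        rows.append((step, cand.name, current.ofv_, trial.ofv_, delta, "removed"))
        retained.remove(cand)
        current = trial
    trace = pd.DataFrame(
        rows, columns=["step", "candidate", "ofv_full", "ofv_reduced",
                       "delta_ofv", "decision"],
    )
    current.retained_candidates_ = tuple(retained)
    return current, trace
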