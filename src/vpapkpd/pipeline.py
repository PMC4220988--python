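"""End-to-end analysis runner: generate -> filter -> fit PK -> freeze AUC ->
fit PD -> select -> bootstrap -> VPC -> risk table.

Estimation is sequential (two-stage): the individual PK parameters are fixed
after the PK stage and the PD stage consumes the frozen empirical Bayes AUC
values, so re-running the PD stage never alters PK artifacts.  A master seed
spawns one child seed per stage deterministically, letting any stage be
re-run in isolation; every run writes a manifest recording the config, the
stage seeds and the artifact inventory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .dataset import (
    Cohort,
    default_uln_table,
    filter_early_ggt,
    flag_noncompliance,
    load_cohort,
    load_uln_table,
    qc_report,
    write_cohort,
)
from .pd_model import DEFAULT_PD_TRUTH, GGTElevationModel, build_pd_table
from .pk_model import DEFAULT_PK_TRUTH, DEFAULT_PK_VARIANCE, PopulationPKModel
from .risk import simulate_risk
from .selection import CandidateCovariate, backward_elimination, forward_inclusion
from .validation import bootstrap as run_bootstrap
from .validation import gof_diagnostics, vpc as run_vpc

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "fit_pk", "fit_pd", "select", "bootstrap", "vpc", "risk")


@dataclass
class RunConfig:
    outdir: str = "runs/run"
    seed: int = 1
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort_csv: str | None = None  # when set, 'generate' is skipped and data loaded
    uln_csv: str | None = None
    n_subjects: int = 169
    loq: float = 1.0
    min_months: float = 6.0
    pd_selection_candidates: tuple = ("intellectual_disability", "sod2_valval")
    selection_exclusions: tuple = ()  # user-supplied multicollinearity prunes
    bootstrap_n: int = 1000
    vpc_n_sim: int = 1000
    risk_doses: tuple = (400, 500, 600, 700, 800, 900, 1000, 1100, 1200)
    risk_n: int = 1000
    risk_replicates: int = 200
    risk_omega2_logit: float | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {s: int(c.generate_state(1)[0] % (2**31))
                for s, c in zip(STAGES, children)}


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure raises with the stage name; artifacts written by the
    stages that already completed are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest = {"seed": config.seed, "stage_seeds": seeds, "artifacts": [],
                "config": dataclasses.asdict(config)}

    def record(name):
        manifest["artifacts"].append(name)

    uln = load_uln_table(config.uln_csv) if config.uln_csv else default_uln_table()
    cohort = None
    stage = "generate"
    try:
        if config.stages.get("generate", False):
            gen_cfg = dataclasses.replace(
                synthetic.pd_cohort_config(), n_subjects=config.n_subjects
            )
            cohort, _ = synthetic.generate_full_cohort(
                gen_cfg, DEFAULT_PK_TRUTH, DEFAULT_PK_VARIANCE, DEFAULT_PD_TRUTH,
                seeds["generate"], uln,
            )
            write_cohort(cohort, out / "cohort.csv")
            uln.write_csv(out / "uln.csv")
            _dump_json(qc_report(cohort), out / "qc_report.json")
            record("cohort.csv"); record("uln.csv"); record("qc_report.json")
        elif config.cohort_csv:
            cohort = load_cohort(config.cohort_csv, uln)
        if cohort is not None:
            kept, excluded = flag_noncompliance(cohort.pk_records, config.loq)
            ggt = filter_early_ggt(cohort.ggt_records, config.min_months)
            cohort = Cohort(cohort.subjects, kept, ggt)
            manifest["n_conc_excluded_loq"] = len(excluded)

        pk_fit = None
        if config.stages.get("fit_pk", False):
            stage = "fit_pk"
            pk_fit = PopulationPKModel().fit(cohort)
            _dump_json({"theta": pk_fit.theta_, "omega2": pk_fit.omega2_,
                        "sigma2": pk_fit.sigma2_, "ofv": pk_fit.ofv_,
                        "converged": pk_fit.converged_}, out / "pk_fit.json")
            gof = gof_diagnostics(cohort, pk_fit)
            gof.to_csv(out / "pk_gof.csv", index=False)
            if config.plots:
                from .plots import plot_gof

                plot_gof(gof, out / "pk_gof.png")
                record("pk_gof.png")
            pk_fit.auc_.rename_axis("subject_id").to_frame().to_csv(out / "pk_auc.csv")
            record("pk_fit.json"); record("pk_gof.csv"); record("pk_auc.csv")

        pd_fit = None
        table = None
        if config.stages.get("fit_pd", False):
            stage = "fit_pd"
            # sequential two-stage estimation: AUCs frozen from the PK stage
            table = build_pd_table(cohort, pk_fit.auc_)
            table.to_csv(out / "pd_table.csv", index=False)
            pd_fit = GGTElevationModel().fit(table)
            _dump_json({**pd_fit.fitted_params(), "ofv": pd_fit.ofv_,
                        "converged": pd_fit.converged_}, out / "pd_fit.json")
            record("pd_table.csv"); record("pd_fit.json")

        if config.stages.get("select", False):
            stage = "select"
            candidates = [
                CandidateCovariate(name, param="covariates")
                for name in config.pd_selection_candidates
                if name not in config.selection_exclusions
            ]
            base = GGTElevationModel(covariates=())
            full, ftrace = forward_inclusion(base, table, candidates)
            final, btrace = backward_elimination(
                base, table, list(getattr(full, "included_candidates_", ())),
            )
            ftrace.to_csv(out / "selection_forward.csv", index=False)
            btrace.to_csv(out / "selection_backward.csv", index=False)
            record("selection_forward.csv"); record("selection_backward.csv")

        if config.stages.get("bootstrap", False):
            stage = "bootstrap"
            strata = {s.subject_id: (s.sod2_valval, s.intellectual_disability)
                      for s in cohort.subjects}
            bres = run_bootstrap(table, GGTElevationModel(), n=config.bootstrap_n,
                                 strata=strata, seed=seeds["bootstrap"])
            bres.summary.to_csv(out / "bootstrap_summary.csv")
            _dump_json({"n_requested": bres.n_requested,
                        "n_successful": bres.n_successful,
                        "unreliable": bres.unreliable}, out / "bootstrap_meta.json")
            record("bootstrap_summary.csv"); record("bootstrap_meta.json")

        if config.stages.get("vpc", False):
            stage = "vpc"
            vres = run_vpc(table, pd_fit, n_sim=config.vpc_n_sim,
                           strata=("sod2_valval", "intellectual_disability"),
                           seed=seeds["vpc"])
            vres.to_csv(out / "vpc.csv", index=False)
            record("vpc.csv")
            if config.plots:
                from .plots import plot_vpc

                plot_vpc(vres, out / "vpc.png")
                record("vpc.png")

        if config.stages.get("risk", False):
            stage = "risk"
            pk_params = DEFAULT_PK_TRUTH if pk_fit is None else _pk_thetas_from_fit(pk_fit)
            pd_params = DEFAULT_PD_TRUTH if pd_fit is None else pd_fit.to_pd_parameters()
            omega2_cl = (pk_fit.omega2_.get("cl", 0.0587) if pk_fit is not None
                         else 0.0587)
            risk = simulate_risk(
                pk_params, pd_params, config.risk_doses, n=config.risk_n,
                n_replicates=config.risk_replicates, omega2_cl=omega2_cl,
                omega2_logit=config.risk_omega2_logit, seed=seeds["risk"],
            )
            risk.to_csv(out / "risk_table.csv", index=False)
            record("risk_table.csv")
    except Exception as exc:
        _dump_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _dump_json(manifest, out / "manifest.json")
    record("manifest.json")
    return out


def _pk_thetas_from_fit(pk_fit: PopulationPKModel):
    from .pk_model import PKThetas

    th = pk_fit.theta_
    return PKThetas(
        ka=th["ka"], cl=th["cl"], vd=th["vd"], alag=pk_fit.alag,
        dose_exp_cl=th.get("cl:dose", 0.0), dose_exp_vd=th.get("vd:dose", 0.0),
        factor_female=th.get("cl:female", 1.0), factor_cbz=th.get("cl:CBZ", 1.0),
        factor_clb=th.get("cl:CLB", 1.0), factor_pb=th.get("cl:PB", 1.0),
        factor_pht=th.get("cl:PHT", 1.0),
    )
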