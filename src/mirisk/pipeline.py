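"""End-to-end orchestration: simulate/ingest -> preprocess -> describe ->
Cox incremental value -> hazard tree + bagging -> risk metrics -> report.

One YAML config and one top-level seed govern the whole run; every stage
persists its artifact (CSV/JSON) into the output directory so each number in
the final report can be recomputed from intermediates.  A stage failure
yields a partial report with the failure context; downstream stages are
skipped.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import SurvivalCohort
from .cohort_stats import baseline_table, baseline_table_frame
from .cox import harrell_cindex
from .errors import ConfigurationError, MiriskError
from .incremental_value import MODEL_COVARIATES, cnri_idi, mirna_association
from .io import CohortSchema, preprocess, read_cohort, write_cohort, write_json
from .risk_metrics import node_summary_frame, tree_metrics
from .synthetic import default_cohort_spec, default_truth, generate_cohort
from .tree import TreeParams, bagging_select, grow_tree

DEFAULT_TREE_VARIABLES = [
    "age", "asv", "male", "sbp_lt_120", "diabetes", "diuretic",
    "cardiac_device", "walk_distance", "atrial_fibrillation",
    "log_nt_probnp", "mir133a",
]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int
    n_subjects: int = 587
    cohort_path: str | None = None      # when set, ingest instead of simulate
    mirna: str = "mir133a"
    log_columns: list[str] = field(default_factory=lambda: ["nt_probnp", "mir133a"])
    tree_variables: list[str] = field(default_factory=lambda: list(DEFAULT_TREE_VARIABLES))
    tree_params: TreeParams = field(default_factory=TreeParams)
    bagging_B: int = 50
    retention_threshold: float = 0.5
    iauc_window: tuple[float, float] = (0.25, 5.0)
    reclassification_horizon: float = 2.0
    n_resample: int = 300
    metrics_n_boot: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "outdir" not in raw or "seed" not in raw:
            raise ConfigurationError("config requires 'outdir' and 'seed'")
        tp = TreeParams(**raw.get("tree_params", {}))
        kwargs = {
            k: raw[k]
            for k in (
                "n_subjects", "cohort_path", "mirna", "log_columns",
                "tree_variables", "bagging_B", "retention_threshold",
                "reclassification_horizon", "n_resample", "metrics_n_boot",
            )
            if k in raw
        }
        if "iauc_window" in raw:
            kwargs["iauc_window"] = tuple(raw["iauc_window"])
        return cls(outdir=raw["outdir"], seed=int(raw["seed"]), tree_params=tp, **kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["iauc_window"] = list(self.iauc_window)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StageResult:
    name: str
    status: str                      # ok | failed | skipped
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    wall_time: float = 0.0
    error: str | None = None


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stages: list[StageResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _validate_config(cfg: PipelineConfig) -> None:
    """Fail before any compute on covariates the run cannot provide."""
    if cfg.cohort_path is None:
        available = set(default_cohort_spec().covariate_names)
        available |= {f"log_{c}" for c in cfg.log_columns}
        unknown = [v for v in cfg.tree_variables if v not in available]
        if unknown:
            raise ConfigurationError(
                f"tree variables not produced by the simulation/preprocessing: {unknown}"
            )
        if cfg.mirna not in available:
            raise ConfigurationError(f"mirna '{cfg.mirna}' not available")


def run_pipeline(config: PipelineConfig) -> RunReport:
    _validate_config(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )
    write_json(config.to_dict(), out / "config_resolved.json")

    state: dict = {}
    failed = False

    def stage(name):
        def deco(fn):
            nonlocal failed
            res = StageResult(name=name, status="skipped")
            if failed:
                report.stages.append(res)
                return
            t0 = _time.perf_counter()
            try:
                import warnings as _w

                with _w.catch_warnings(record=True) as caught:
                    _w.simplefilter("always")
                    res.outputs = fn(state) or []
                res.warnings = [str(c.message) for c in caught]
                res.status = "ok"
            except MiriskError as exc:
                res.status = "failed"
                res.error = f"{type(exc).__name__}: {exc}"
                failed = True
            res.wall_time = _time.perf_counter() - t0
            report.stages.append(res)

        return deco

    @stage("ingest")
    def _ingest(st):
        if config.cohort_path is not None:
            cohort, parse = read_cohort(config.cohort_path, CohortSchema())
            st["truth"] = None
        else:
            cohort, truth = generate_cohort(
                default_cohort_spec(config.n_subjects), default_truth(), config.seed
            )
            truth.to_json(out / "truth.json")
            st["truth"] = truth
        st["cohort"] = cohort
        write_cohort(cohort, out / "cohort.csv")
        return ["cohort.csv"]

    @stage("preprocess")
    def _prep(st):
        log_cols = [c for c in config.log_columns if c in st["cohort"].data.columns]
        st["cohort"] = preprocess(st["cohort"], log_cols)
        write_cohort(st["cohort"], out / "cohort_analysis.csv")
        return ["cohort_analysis.csv"]

    @stage("describe")
    def _desc(st):
        rows = baseline_table(
            st["cohort"].data, "event",
            variables=[v for v in st["cohort"].covariate_names],
        )
        baseline_table_frame(rows).to_csv(out / "baseline_by_outcome.csv", index=False)
        return ["baseline_by_outcome.csv"]

    @stage("cox_models")
    def _cox(st):
        cohort = st["cohort"]
        mir_log = f"log_{config.mirna}" if f"log_{config.mirna}" in cohort.data.columns \
            else config.mirna
        results = {}
        crude = mirna_association(cohort, mir_log, model=None)
        results["crude"] = _fit_to_dict(crude, mir_log)
        for mid in (1, 2, 3):
            covs = [c for c in MODEL_COVARIATES[mid] if c in cohort.data.columns]
            from .incremental_value import ModelSpec

            f = mirna_association(cohort, mir_log, model=ModelSpec(mid, covs))
            results[f"model_{mid}"] = _fit_to_dict(f, mir_log)
            sub = cohort.data[["time", "event"] + covs + [mir_log]].dropna()
            lp = f.linear_predictor(sub[covs + [mir_log]].to_numpy(float))
            results[f"model_{mid}"]["c_index_with_mirna"] = harrell_cindex(
                lp, sub["time"].to_numpy(float), sub["event"].to_numpy()
            )
        # reclassification for the largest model that excludes NT-proBNP (model 2)
        covs2 = [c for c in MODEL_COVARIATES[2] if c in cohort.data.columns]
        rec = cnri_idi(
            cohort.data, covs2, covs2 + [mir_log],
            horizon=config.reclassification_horizon,
            n_resample=config.n_resample,
            seed=config.seed,
        )
        results["reclassification_model2"] = {
            "horizon": rec.horizon,
            "cNRI": rec.cnri, "cNRI_ci": list(rec.cnri_ci), "cNRI_p": rec.cnri_p,
            "IDI": rec.idi, "IDI_ci": list(rec.idi_ci), "IDI_p": rec.idi_p,
            "n": rec.n,
        }
        write_json(results, out / "cox_models.json")
        return ["cox_models.json"]

    @stage("tree")
    def _tree(st):
        cohort = st["cohort"]
        vars_avail = [v for v in config.tree_variables if v in cohort.data.columns]
        tree = grow_tree(cohort, vars_avail, config.tree_params, seed=config.seed)
        st["tree"] = tree
        tree.to_json(out / "tree.json")
        (out / "tree.txt").write_text(tree.render() + "\n")
        return ["tree.json", "tree.txt"]

    @stage("bagging")
    def _bag(st):
        cohort = st["cohort"]
        vars_avail = [v for v in config.tree_variables if v in cohort.data.columns]
        rep = bagging_select(
            cohort, vars_avail, B=config.bagging_B, params=config.tree_params,
            seed=config.seed, retention_threshold=config.retention_threshold,
            iauc_window=config.iauc_window,
        )
        st["bagging"] = rep
        rep.to_json(out / "bagging.json")
        return ["bagging.json"]

    @stage("metrics")
    def _metrics(st):
        tm = tree_metrics(
            st["tree"], st["cohort"],
            t0=config.iauc_window[0], t1=config.iauc_window[1],
            n_boot=config.metrics_n_boot, seed=config.seed,
        )
        st["metrics"] = tm
        node_summary_frame(tm.summaries).to_csv(out / "node_summaries.csv", index=False)
        write_json(
            {
                "N": tm.N,
                "n_terminal_nodes": tm.f,
                "overall_incidence_rate": tm.overall_ir,
                "IRV": tm.irv,
                "iAUC": tm.iauc.iauc,
                "iAUC_ci": [tm.iauc.ci_low, tm.iauc.ci_high],
                "auc_times": tm.iauc.auc_times,
                "auc_values": tm.iauc.auc_values,
                "risk_bands": {str(k): v for k, v in tm.banding.assignment.items()},
            },
            out / "metrics.json",
        )
        return ["metrics.json", "node_summaries.csv"]

    write_json(report.to_dict(), out / "run_report.json")
    return report


def _fit_to_dict(fit, focus: str) -> dict:
    ci = fit.confidence_intervals()
    j = fit.covariates.index(focus)
    return {
        "covariates": fit.covariates,
        "n": fit.n,
        "events": fit.n_events,
        "converged": fit.converged,
        "HR": float(fit.hazard_ratios[j]),
        "HR_ci": [float(ci[j, 0]), float(ci[j, 1])],
        "p": float(fit.p_values[j]),
    }
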