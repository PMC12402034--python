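"""End-to-end orchestration.

Assembles the four model settings — diagnosis (D) and prognosis (P), each
under the Environmental (ENV) and Healthcare (HEA = ENV ∪ CLI) scenarios —
and runs the full analysis: simulate → geospatial augmentation → feature
engineering → imputation → quasi-constancy filtering → permutation
importance → backward SFS → hyperparameter tuning → 10-fold evaluation →
partial dependence. Every stage receives an independent seed derived from
one master seed, so stages are independently reproducible.

Task assembly rules: individuals with known (pre-study) T2D are excluded
from every task; the diagnosis label is T2D newly diagnosed at baseline;
the prognosis sample additionally drops baseline-diagnosed individuals and
those without complete follow-up, and its label is incident T2D.
Explanatory variables are always baseline values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engineering, geospatial, imputation, quasiconstancy
from .cohort import CohortBundle, CohortConfig, generate_cohort, inject_missingness
from .errors import DataError
from .modeling import (DEFAULT_SEARCH_SPACE, SMOKE_XGB_PARAMS, ModelParams,
                       crossval_evaluate, partial_dependence,
                       tune_hyperparameters)
from .selection import backward_sfs, permutation_importance, significant_features

__all__ = ["TaskSpec", "PipelineConfig", "ReportBundle", "build_task_sample",
           "run_pipeline"]

logger = logging.getLogger("t2drisk")

TASKS = ("diagnosis", "prognosis")
SCENARIOS = ("ENV", "HEA")


@dataclass(frozen=True)
class TaskSpec:
    task: str       # 'diagnosis' | 'prognosis'
    scenario: str   # 'ENV' | 'HEA'

    @property
    def model_id(self) -> str:
        return f"{'D' if self.task == 'diagnosis' else 'P'}-{self.scenario}"

    @property
    def label_column(self) -> str:
        return ("baseline_new_diagnosis" if self.task == "diagnosis"
                else "incident_t2d")


def build_task_sample(cohort: CohortBundle, spec: TaskSpec):
    """Rows, labels and region groups for one task/scenario.

    Returns (table of masked values, binary labels, region group labels).
    Exclusion counts are logged, giving a flow-diagram-style accounting.
    """
    labels = cohort.labels
    for col in ("known_t2d", "baseline_new_diagnosis", "in_followup",
                "followup_complete", "incident_t2d"):
        if col not in labels.columns:
            raise DataError(f"label column {col!r} missing")
    keep = ~labels["known_t2d"]
    logger.info("%s: excluded %d known-T2D individuals",
                spec.model_id, int((~keep).sum()))
    if spec.task == "prognosis":
        before = int(keep.sum())
        keep &= ~labels["baseline_new_diagnosis"]
        keep &= labels["in_followup"] & labels["followup_complete"]
        logger.info("%s: excluded %d baseline-diagnosed or follow-up-incomplete",
                    spec.model_id, before - int(keep.sum()))

    meta = cohort.metadata
    if spec.scenario == "ENV":
        cols = [c for c in cohort.values.columns if meta.loc[c, "domain"] == "ENV"]
    else:
        cols = [c for c in cohort.values.columns
                if meta.loc[c, "domain"] in ("ENV", "CLI")]
    rows = keep[keep].index
    table = cohort.values.loc[rows, cols].where(cohort.mask.loc[rows, cols])
    y = labels.loc[rows, spec.label_column].astype(int)
    groups = geospatial.region_groups(cohort).loc[rows]
    return table, y, groups


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    idw_beta: float = 2.0
    idw_k: int = 10
    qs_threshold: float = 0.7
    quasi_constancy_threshold: float = 0.05
    pi_reps: int = 100
    sfs_reps: int = 100
    test_fraction: float = 0.3
    tune_trials: int = 100
    tune_folds: int = 20
    eval_folds: int = 10
    model_params: dict = field(default_factory=lambda: dict(SMOKE_XGB_PARAMS))
    run_tuning: bool = True
    run_pdp: bool = True
    seed: int = 0

    @staticmethod
    def smoke(seed: int = 0) -> "PipelineConfig":
        """Minutes-scale configuration on one CPU."""
        return PipelineConfig(
            cohort=CohortConfig.smoke(seed=seed),
            pi_reps=10, sfs_reps=10, tune_trials=5, tune_folds=4,
            eval_folds=4, run_tuning=False, seed=seed)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = PipelineConfig(**raw)
        if cohort_raw:
            cfg.cohort = CohortConfig(**cohort_raw)
        return cfg

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["cohort"] = {k: v for k, v in asdict(self.cohort).items()
                         if not isinstance(v, (dict, tuple))}
        Path(path).write_text(yaml.safe_dump(doc, default_flow_style=False))


@dataclass
class ReportBundle:
    cohort_counts: dict
    model_reports: dict  # model id -> dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cohort_counts.json").write_text(json.dumps(self.cohort_counts, indent=1))
        for model_id, report in self.model_reports.items():
            serializable = {k: v for k, v in report.items() if k != "pdp"}
            (out / f"report_{model_id}.json").write_text(
                json.dumps(serializable, indent=1, default=_json_default))
            for feat, curve in report.get("pdp", {}).items():
                pd.DataFrame({"grid": curve.grid, "response": curve.response}) \
                    .to_csv(out / f"pdp_{model_id}_{feat}.csv", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig, out_dir=None) -> ReportBundle:
    """Run the full analysis for all four models (D-ENV, D-HEA, P-ENV,
    P-HEA) and return (optionally also write) the report bundle."""
    cohort_cfg = CohortConfig(**{**asdict_shallow(config.cohort),
                                 "seed": _stage_seed(config.seed, "cohort")})
    bundle = generate_cohort(cohort_cfg)
    bundle = inject_missingness(bundle, cohort_cfg)
    bundle = geospatial.augment_cohort_geospatial(
        bundle, cfg=geospatial.IDWConfig(beta=config.idw_beta, k=config.idw_k))
    bundle = engineering.engineer_features(bundle)

    cohort_counts = dict(
        n_individuals=bundle.n_individuals,
        n_known_t2d=int(bundle.labels["known_t2d"].sum()),
        n_features_env=len(bundle.feature_names("ENV")),
        n_features_cli=len(bundle.feature_names("CLI")),
    )
    reports = {}
    for task in TASKS:
        for scenario in SCENARIOS:
            spec = TaskSpec(task, scenario)
            reports[spec.model_id] = _run_model(bundle, spec, config)
            reports[spec.model_id]["n_rows"] = reports[spec.model_id].pop("n")
    cohort_counts["n_diagnosis_eligible"] = reports["D-ENV"]["n_rows"]
    cohort_counts["n_prognosis_eligible"] = reports["P-ENV"]["n_rows"]
    result = ReportBundle(cohort_counts=cohort_counts, model_reports=reports)
    if out_dir is not None:
        result.save(out_dir)
    return result


def asdict_shallow(dc) -> dict:
    """dataclasses.asdict without recursing into nested dataclasses."""
    return {f: getattr(dc, f) for f in dc.__dataclass_fields__}


def _run_model(bundle: CohortBundle, spec: TaskSpec,
               config: PipelineConfig) -> dict:
    seed = _stage_seed(config.seed, spec.model_id)
    X_raw, y, groups = build_task_sample(bundle, spec)
    n = len(X_raw)

    imp_cfg = imputation.ImputationConfig(retention_threshold=config.qs_threshold)
    plan = imputation.select_imputers(X_raw, seed=seed, config=imp_cfg)
    X = imputation.apply_imputation(plan, X_raw, seed=seed)
    logger.info("%s: imputation retained %d/%d features",
                spec.model_id, len(plan.retained_features()), X_raw.shape[1])

    retained, qc_results = quasiconstancy.filter_quasi_constant(
        X, threshold=config.quasi_constancy_threshold)
    X = X[retained]
    logger.info("%s: quasi-constancy retained %d features",
                spec.model_id, len(retained))

    pi = permutation_importance(
        X, y, groups, model_params=config.model_params, n_reps=config.pi_reps,
        test_fraction=config.test_fraction, seed=seed)
    sig = significant_features(pi)
    logger.info("%s: %d significant features", spec.model_id, len(sig))

    if len(sig) >= 2:
        trace = backward_sfs(X, y, groups, start_features=sig,
                             model_params=config.model_params,
                             n_reps=config.sfs_reps,
                             test_fraction=config.test_fraction, seed=seed)
        selected = trace.selected
        sfs_summary = dict(start_score=trace.start_score,
                           removals=trace.removals,
                           selected_score=trace.selected_score)
    else:
        # too few significant features for a backward search; fall back to
        # the single best-ranked feature pair by mean drop
        fallback = list(pi.mean_drop.sort_values(ascending=False).index[:2])
        selected = sig if sig else fallback[:1]
        sfs_summary = dict(skipped=True)
        logger.info("%s: SFS skipped (%d significant features)",
                    spec.model_id, len(sig))

    if config.run_tuning:
        tuned = tune_hyperparameters(
            X[selected], y, groups, space=DEFAULT_SEARCH_SPACE,
            n_folds=config.tune_folds, n_trials=config.tune_trials, seed=seed)
        params = {**config.model_params, **tuned.params}
    else:
        tuned = ModelParams(params=dict(config.model_params))
        params = dict(config.model_params)

    evaluation = crossval_evaluate(X[selected], y, groups, params,
                                   k=config.eval_folds, seed=seed)

    pdp = {}
    if config.run_pdp:
        from .modeling import make_classifier
        model = make_classifier(params, seed=seed)
        model.fit(X[selected], y)
        for feat in selected:
            pdp[feat] = partial_dependence(model, X[selected], feat,
                                           group_labels=y)

    thr = evaluation.threshold_summary()
    return dict(
        model=spec.model_id, task=spec.task, scenario=spec.scenario, n=n,
        n_features_start=X_raw.shape[1],
        n_features_after_preprocessing=len(retained),
        significant_features=sig, selected_features=list(selected),
        sfs=sfs_summary, tuned_params=tuned.params,
        mean_auroc=evaluation.mean_auroc, auroc_ci=list(evaluation.ci),
        fold_auroc=evaluation.fold_auroc.tolist(),
        youden_metrics={k: dict(mean=float(thr.loc[k, "mean"]),
                                sd=float(thr.loc[k, "sd"]))
                        for k in thr.index},
        quasi_constancy_dropped=[r.feature for r in qc_results if not r.retained],
        imputation_dropped=[f for f, e in plan.entries.items()
                            if not e["retained"]],
        pdp=pdp,
    )
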