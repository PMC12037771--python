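"""End-to-end orchestration: simulate -> classify -> preprocess -> train -> report.

``run_all`` executes the full analysis: (optionally) simulate a cohort,
derive responder labels from the VTT trajectories, preprocess the baseline
feature table, run the LOOCV predictor, assemble the week-3 fold-change
features and rerun (the "dynamic" model), and write a side-by-side report.
Every artifact records the master seed and a hash of the configuration, and
rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import preprocess as prep
from . import predictor as pred
from .cohort import CohortSpec, SyntheticCohort, generate_cohort
from .containers import FeatureTable
from .exceptions import ConfigurationError
from .response import classify_cohort, labels_series

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    simulate: bool = True
    cohort: CohortSpec | None = None
    pipeline: pred.PipelineConfig = field(default_factory=pred.PipelineConfig)
    features_path: str | None = None
    vtt_path: str | None = None
    plasma_path: str | None = None
    dynamic_week: int = 3

    def __post_init__(self) -> None:
        if not self.simulate:
            for p, what in ((self.features_path, "features"),
                            (self.vtt_path, "vtt"), (self.plasma_path, "plasma")):
                if p is None:
                    raise ConfigurationError(f"{what} path required when not simulating")
                if not Path(p).exists():
                    raise ConfigurationError(f"{what} file not found: {p}")


def config_hash(config: RunConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("outdir", None)  # where results land is not part of the science
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_features(path: str, meta_path: str | None = None) -> FeatureTable:
    values = pd.read_csv(path, index_col=0)
    meta = None
    if meta_path and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, index_col=0)
    return FeatureTable(values, meta)


def result_to_dict(result: pred.LOOResult) -> dict:
    return {
        "metrics": result.metrics(),
        "iterations": [
            {"left_out": it.left_out_id,
             "selected_features": it.selected_features,
             "weights": it.weights,
             "best_hyperparams": it.best_hyperparams,
             "oof_score": it.oof_score}
            for it in result.iterations],
        "importance": pred.importance_summary(result).reset_index()
                          .to_dict(orient="records"),
        "labels": {p: int(l) for p, l in zip(result.patient_ids, result.labels)},
    }


def run_all(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    logger.info("run %s -> %s", chash, outdir)

    # -- stage: inputs -------------------------------------------------------
    if config.simulate:
        spec = config.cohort or CohortSpec(seed=config.seed)
        cohort: SyntheticCohort | None = generate_cohort(spec)
        cohort.write(outdir / "cohort")
        features, vtt, plasma = cohort.features, cohort.vtt, cohort.plasma
        logger.info("stage simulate: %d patients x %d features",
                    features.n_patients, features.n_features)
    else:
        features = _load_features(config.features_path)
        vtt = pd.read_csv(config.vtt_path)
        plasma = pd.read_csv(config.plasma_path)
        logger.info("stage load: %d patients x %d features",
                    features.n_patients, features.n_features)

    # -- stage: classify -----------------------------------------------------
    labels_df = classify_cohort(vtt)
    labels_df.to_csv(outdir / "labels.csv")
    y = labels_series(labels_df)
    logger.info("stage classify: %d/%d responders", int(y.sum()), len(y))

    # -- stage: preprocess (reproduction mode: once, on the full table) ------
    pcfg = config.pipeline
    if pcfg.preprocess_mode == "global":
        table_base, _, prune_report = prep.preprocess_table(features, seed=config.seed)
        (outdir / "prune.json").write_text(json.dumps({
            "threshold": prune_report.threshold,
            "dropped": prune_report.dropped,
            "groups": prune_report.groups}, indent=2))
        table_base.values.to_csv(outdir / "preprocessed_baseline.csv")
    else:
        table_base = features
    logger.info("stage preprocess: %d features retained", table_base.n_features)

    # -- stage: baseline model ----------------------------------------------
    res_base = pred.loocv_run(table_base, y, pcfg)
    logger.info("stage train (baseline): pooled AUC %.3f", res_base.pooled_auc())

    # -- stage: dynamic model -------------------------------------------------
    dyn = prep.fold_change_features(plasma, week=config.dynamic_week)
    combined = prep.assemble_dynamic(features, dyn)
    if pcfg.preprocess_mode == "global":
        table_dyn, _, _ = prep.preprocess_table(combined, seed=config.seed)
    else:
        table_dyn = combined
    res_dyn = pred.loocv_run(table_dyn, y, pcfg)
    logger.info("stage train (dynamic): pooled AUC %.3f", res_dyn.pooled_auc())

    # -- stage: report --------------------------------------------------------
    run = {"config_hash": chash, "seed": config.seed,
           "baseline": result_to_dict(res_base),
           "dynamic": result_to_dict(res_dyn)}
    (outdir / "run.json").write_text(json.dumps(run, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(render_report(run))
    return outdir


def run_seed_ensemble(features: FeatureTable, plasma: pd.DataFrame,
                      labels: pd.Series, seeds,
                      config: pred.PipelineConfig | None = None,
                      dynamic_week: int = 3) -> tuple[pd.DataFrame, dict]:
    """Rerun both models across a seed ensemble on one fixed dataset.

    The algorithm's stochastic elements (collinearity-prune tie-breaks,
    inner-fold shuffling, SGD ordering) vary with the seed; the data do not.
    Imputation and scaling are deterministic given the data, so they run
    once per table. Returns a tidy per-seed metric frame (one row per seed
    per model) and a dict of per-seed importance tables
    ``{(seed, model): DataFrame}``.
    """
    config = config or pred.PipelineConfig()
    dyn = prep.fold_change_features(plasma, week=dynamic_week)
    combined = prep.assemble_dynamic(features, dyn)
    complete = {}
    for name, tab in (("baseline", features), ("dynamic", combined)):
        imputed = prep.iterative_impute(tab)
        complete[name], _ = prep.minmax_scale(imputed)

    rows, importances = [], {}
    for seed in seeds:
        for model in ("baseline", "dynamic"):
            pruned, _ = prep.spearman_prune(complete[model], seed=seed)
            cfg = dataclasses.replace(config, seed=int(seed),
                                      preprocess_mode="global")
            res = pred.loocv_run(pruned, labels, cfg)
            rows.append({"seed": int(seed), "model": model, **res.metrics()})
            importances[(int(seed), model)] = pred.importance_summary(res)
    return pd.DataFrame(rows), importances


_METRIC_ROWS = [("AUC ROC", "auc_roc"), ("Accuracy", "accuracy"),
                ("Sensitivity", "sensitivity"), ("Precision", "precision"),
                ("F1-score", "f1"), ("Specificity", "specificity"),
                ("AU PRC", "au_prc")]


def render_report(run: dict, fmt: str = "md") -> str:
    """Side-by-side baseline vs dynamic metric table with <,=,> markers."""
    base, dyn = run["baseline"]["metrics"], run["dynamic"]["metrics"]
    lines = []
    if fmt == "md":
        lines += ["| Metric | Baseline model | | Dynamic model |",
                  "|---|---|---|---|"]
        for label, key in _METRIC_ROWS:
            b, d = base[key], dyn[key]
            op = "<" if b < d else (">" if b > d else "=")
            lines.append(f"| {label} | {b:.3f} | {op} | {d:.3f} |")
    else:
        lines.append("metric,baseline,cmp,dynamic")
        for label, key in _METRIC_ROWS:
            b, d = base[key], dyn[key]
            op = "<" if b < d else (">" if b > d else "=")
            lines.append(f"{label},{b:.6f},{op},{d:.6f}")
    return "\n".join(lines) + "\n"
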