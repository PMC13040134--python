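"""End-to-end orchestration: generate -> extract -> select -> train -> evaluate.

A run is configured by :class:`RunConfig` (YAML/JSON-friendly), executes all
stages with every source of randomness seeded, and writes a run directory

    features.csv, features_meta.json   feature matrix + provenance
    selection.json                     p-values, adjusted p, kept features
    model_<name>.json                  algorithm, hyperparameters, CV AUC
    predictions.csv                    case_id, model_id, risk
    report.json                        the full evaluation battery
    curves_calibration_<name>.csv      calibration curve points
    curves_decision.csv                net-benefit grid
    manifest.json                      config echo, seeds, artifact hashes

Rerunning with an identical config reproduces identical artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .adnex import adnex_risk_frame, compare_models
from .features import extract_cohort_features
from .modeling import (RiskModel, SplitSpec, events_per_variable, gain_importance,
                       predict_risk, stratified_split, tune_and_train)
from .selection import MWUBHSelector, SelectionResult
from .synthetic import (CohortSpec, EffectSizes, cohort_clinical_frame,
                        generate_adnex_inputs, generate_cohort, read_cohort)

log = logging.getLogger("adnexrad.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults equal the analysis parameters of the workflow this package
    implements: BH alpha 0.05, |r| threshold 0.6, 70:30 stratified split,
    a 10% risk-of-malignancy cutoff reported alongside the Youden-optimal
    cutoff, and 5-fold randomized-search tuning.
    """

    cohort: CohortSpec | None = None
    input_dir: str | None = None
    output_dir: str = "run"
    n_bins: int = 32
    wiener_kernel: int = 3
    alpha: float = 0.05
    r_threshold: float = 0.6
    train_fraction: float = 0.70
    split_seed: int = 0
    algorithms: tuple[str, ...] = ("gradient_boosted_trees",)
    train_clinical: bool = True
    clinical_algorithm: str = "gradient_boosted_trees"
    cutoff: float = 0.10
    n_search: int = 25
    cv_folds: int = 5
    n_boot: int = 2000
    eval_seed: int = 0
    with_adnex: bool = False

    def validate(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("exactly one of cohort / input_dir must be given")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "cohort" in raw and raw["cohort"] is not None:
            c = dict(raw["cohort"])
            if "effect_sizes" in c and isinstance(c["effect_sizes"], dict):
                c["effect_sizes"] = EffectSizes(**c["effect_sizes"])
            if "class_mix" in c:
                c["class_mix"] = tuple(c["class_mix"])
            raw["cohort"] = CohortSpec(**c)
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()  # numpy scalar
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dumps(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=_json_default)


def _metrics_block(risks: np.ndarray, y: np.ndarray, cutoff: float,
                   n_boot: int, seed: int) -> dict:
    point, ci = ev.auc(risks, y, n_boot=n_boot, seed=seed)
    at_cut = ev.metrics_at_cutoff(risks, y, cutoff)
    yc, j = ev.youden_cutoff(risks, y)
    at_youden = ev.metrics_at_cutoff(risks, y, min(max(yc, 1e-6), 1 - 1e-6))
    return {
        "auc": point, "auc_ci": list(ci),
        "at_cutoff": at_cut.as_row(), "cutoff_ci": {k: list(v) if v else None
                                                    for k, v in at_cut.ci.items()},
        "youden": {"cutoff": yc, "J": j, "metrics": at_youden.as_row()},
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "cohort"
    try:
        if config.cohort is not None:
            cohort = generate_cohort(config.cohort)
        else:
            cohort = read_cohort(config.input_dir)
        clinical = cohort_clinical_frame(cohort)
        log.info("stage %s: %d cases (%.1fs)", stage, len(cohort), time.time() - t0)

        stage = "extract"
        features = extract_cohort_features(cohort, n_bins=config.n_bins,
                                           kernel=config.wiener_kernel)
        features.to_csv(out / "features.csv")
        (out / "features_meta.json").write_text(json.dumps({
            "n_bins": config.n_bins, "wiener_kernel": config.wiener_kernel,
            "n_features": features.shape[1], "registry_version": 1}, indent=2))

        stage = "split"
        train_ids, val_ids = stratified_split(
            cohort, SplitSpec(train_fraction=config.train_fraction,
                              seed=config.split_seed))
        y = clinical["malignant"]
        X_tr, X_va = features.loc[train_ids], features.loc[val_ids]
        y_tr, y_va = y.loc[train_ids], y.loc[val_ids]

        stage = "select"
        selector = MWUBHSelector(alpha=config.alpha, r_threshold=config.r_threshold)
        selector.fit(X_tr, y_tr)
        selector.result_.to_json(out / "selection.json")
        kept = selector.kept_
        log.info("stage select: %d significant, %d kept",
                 len(selector.significant_), len(kept))

        stage = "train"
        models: dict[str, RiskModel] = {}
        for alg in config.algorithms:
            models[f"radiomics_{alg}"] = tune_and_train(
                alg, X_tr[kept], y_tr, cv_folds=config.cv_folds,
                n_search=config.n_search, seed=config.split_seed)
        if config.train_clinical:
            clin_cols = ["age", "ca125"]
            Xc_tr = pd.concat([X_tr[kept], clinical.loc[train_ids, clin_cols]], axis=1)
            models[f"clinical_radiomics_{config.clinical_algorithm}"] = tune_and_train(
                config.clinical_algorithm, Xc_tr, y_tr, cv_folds=config.cv_folds,
                n_search=config.n_search, seed=config.split_seed)
        for name, model in models.items():
            (out / f"model_{name}.json").write_text(_dumps({
                "algorithm": model.algorithm,
                "hyperparameters": dict(model.best_params_),
                "cv_auc": model.cv_auc_, "features": model.feature_names_,
                "seed": model.random_state}))

        stage = "evaluate"
        preds = []
        report: dict = {"n_train": len(train_ids), "n_validation": len(val_ids),
                        "n_validation_events": int(y_va.sum()),
                        "selection": {"n_significant": len(selector.significant_),
                                      "n_kept": len(kept), "kept": kept}}
        risks_val: dict[str, np.ndarray] = {}
        for name, model in models.items():
            Xv = X_va[kept]
            if name.startswith("clinical"):
                Xv = pd.concat([X_va[kept], clinical.loc[val_ids, ["age", "ca125"]]],
                               axis=1)
            r = model.predict_risk(Xv)
            risks_val[name] = r
            preds.append(predict_risk(model, Xv, model_id=name))
            block = _metrics_block(r, y_va.to_numpy(), config.cutoff,
                                   config.n_boot, config.eval_seed)
            block["cv_auc"] = model.cv_auc_
            n_pred = len(model.feature_names_)
            epv, flagged = events_per_variable(int(y_va.sum()), n_pred)
            block["epv"] = {"ratio": epv, "n_events": int(y_va.sum()),
                            "n_predictors": n_pred, "flagged_below_10": flagged}
            if model.algorithm in ("random_forest", "gradient_boosted_trees"):
                block["gain_importance"] = gain_importance(model)
            try:
                cal = ev.calibration(r, y_va.to_numpy())
                block["calibration"] = {
                    "intercept": cal.intercept, "intercept_ci": list(cal.intercept_ci),
                    "slope": cal.slope, "slope_ci": list(cal.slope_ci)}
                cal.curve.to_csv(out / f"curves_calibration_{name}.csv", index=False)
            except Exception as exc:  # non-convergence reported, not fatal
                block["calibration"] = {"error": str(exc)}
            report[name] = block
        pd.concat(preds).to_csv(out / "predictions.csv", index=False)

        dc = ev.decision_curve(risks_val, y_va.to_numpy())
        dc.to_csv(out / "curves_decision.csv", index=False)

        xgb_models = {n: m for n, m in models.items()
                      if m.algorithm == "gradient_boosted_trees"
                      and not n.startswith("clinical")}
        if xgb_models:
            name, model = next(iter(xgb_models.items()))
            tab = ev.shap_overfit_table(model, X_tr[kept], X_va[kept])
            report["overfit_table"] = tab.to_dict(orient="records")

        pca_df, pca_summary = ev.manufacturer_pca(
            X_tr[kept], clinical.loc[train_ids, "manufacturer"].to_numpy())
        report["manufacturer_pca"] = pca_summary

        if config.with_adnex:
            adnex_in = generate_adnex_inputs(cohort, seed=config.split_seed)
            adnex = adnex_risk_frame(adnex_in.loc[val_ids])
            risks_val["adnex"] = adnex["risk_malignant"].to_numpy()
            report["adnex"] = _metrics_block(risks_val["adnex"], y_va.to_numpy(),
                                             config.cutoff, config.n_boot,
                                             config.eval_seed)
            table, dl = compare_models(risks_val, y_va.to_numpy(),
                                       seed=config.eval_seed, n_boot=config.n_boot)
            report["model_comparison"] = table.to_dict(orient="records")
            report["delong"] = dl.to_dict(orient="records")

        (out / "report.json").write_text(_dumps(report))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = sorted(p for p in out.iterdir() if p.suffix in (".csv", ".json")
                       and p.name != "manifest.json")
    manifest = {
        "config": config.to_jsonable(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(_dumps(manifest))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out
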