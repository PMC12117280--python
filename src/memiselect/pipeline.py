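"""End-to-end orchestration: generate/load → trial statistics →
T-learner labelling → screened nested cross-validation → SHAP ranking,
written as a reproducible report bundle with a content-hash manifest.

Every stochastic stage receives a seed derived deterministically from the
master seed, so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_seed
from .fold_preprocess import rf_impute_fit, standardize_and_encode
from .hte_tlearner import fit_arm_models, recovery_report
from .interpret_shap import kernel_shap, plot_beeswarm, rank_and_sign
from .nested_eval import default_model_specs, run_nested_cv
from .predictors import PREDICTOR_NAMES, feature_groups
from .synthetic_rct import GeneratorConfig, TrialDataset, generate_trial
from .trial_stats import summarize_remission

log = logging.getLogger("memiselect")

__all__ = ["RunConfig", "run_experiment", "validate_input"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    input_csv: str | None = None  # load instead of generate when set
    n_participants: int = 191
    missing_rate: float = 0.10
    outdir: str = "memiselect_run"
    time_points: tuple[str, ...] = ("post", "1mfu")
    models: tuple[str, ...] = ("random_forest", "svm_rbf", "logistic_reference")
    n_outer: int = 10
    n_inner: int = 5
    n_repeats: int = 2
    top_k: int = 10
    smote_k: int = 5
    impute_max_iter: int = 2
    tlearner_splits: int = 10
    shap_coalitions: int = 512
    shap_background: int = 100
    shap_instances: int = 100
    run_trial_stats: bool = True
    run_tlearner: bool = True
    run_nested: bool = True
    run_shap: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("time_points", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_input(csv_path: str | Path) -> dict:
    """Schema check of a participant-level CSV.

    Verifies the 17 canonical predictor columns, arm coding (0/1 or
    MEMI/SM), the two severity columns, prompt counts in [0, 70], and
    unique participant ids; reports per-column missingness.
    """
    df = pd.read_csv(csv_path)
    errors: list[str] = []
    missing_cols = [c for c in PREDICTOR_NAMES if c not in df.columns]
    if missing_cols:
        errors.append(f"missing predictor columns: {missing_cols}")
    for col in ("participant_id", "arm", "spdq_post", "spdq_1mfu"):
        if col not in df.columns:
            errors.append(f"missing required column: {col}")
    if "participant_id" in df.columns and df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        errors.append(f"duplicate participant ids: {dupes[:5]}")
    if "arm" in df.columns:
        vals = set(df["arm"].dropna().astype(str).str.upper())
        if not vals <= {"0", "1", "0.0", "1.0", "MEMI", "SM"}:
            errors.append(f"arm values outside {{0,1,MEMI,SM}}: {sorted(vals)[:5]}")
    if "prompts_completed" in df.columns:
        pc = df["prompts_completed"].dropna()
        bad = pc[(pc < 0) | (pc > 70)]
        if len(bad):
            errors.append(f"prompt counts outside [0,70]: {bad.tolist()[:5]}")
    present = [c for c in PREDICTOR_NAMES if c in df.columns]
    missingness = (df[present].isna().mean().round(4).to_dict()) if present else {}
    return {"ok": not errors, "errors": errors, "n_rows": len(df), "missingness": missingness}


def _normalize_arm(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["arm"].dtype == object:
        df["arm"] = df["arm"].astype(str).str.upper().map({"MEMI": 1, "SM": 0, "1": 1, "0": 0})
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured stages, writing an artifact bundle.

    Returns the manifest dict (also written to ``manifest.json``): stage
    timings, the data summary (including the masked-cell count), and a
    sha256 per artifact.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"stages": {}, "artifacts": {}}
    t0 = time.time()

    def _stage(name):
        manifest["stages"][name] = round(time.time() - t0, 3)

    if config.input_csv:
        data = TrialDataset.from_csv(config.input_csv)
        report = validate_input(config.input_csv)
        if not report["ok"]:
            raise ValueError(f"input schema errors: {report['errors']}")
        data.df = _normalize_arm(data.df)
    else:
        gen = GeneratorConfig(
            n_participants=config.n_participants,
            missing_rate=config.missing_rate,
            seed=derive_seed(seed, "generate"),
        )
        data = generate_trial(gen)
    data.to_csv(outdir / "dataset.csv")
    manifest["data_summary"] = {
        "n_participants": int(len(data.df)),
        "arm_counts": data.df["arm"].value_counts().to_dict(),
        "masked_cells": data.n_masked_cells,
    }
    _stage("data")

    if config.run_trial_stats:
        summarize_remission(data).to_csv(outdir / "remission_stats.csv", index=False)
        _stage("trial_stats")

    results: dict = {}
    for tp in config.time_points if (config.run_tlearner or config.run_nested) else ():
        tl = fit_arm_models(
            data,
            time_point=tp,
            n_splits=config.tlearner_splits,
            seed=derive_seed(seed, "tlearner", tp),
            impute_max_iter=config.impute_max_iter,
        )
        tl.estimates.to_csv(outdir / f"counterfactuals_{tp}.csv", index=False)
        if data.truth is not None:
            results[f"recovery_{tp}"] = recovery_report(tl, data)
        _stage(f"tlearner_{tp}")
        if not config.run_nested:
            continue

        labels = tl.estimates["optimized"].to_numpy()
        specs = default_model_specs(config.models)
        tables = []
        for label_cfg, screening in (("initial", False), ("final", True)):
            res = run_nested_cv(
                data,
                labels,
                model_specs=specs,
                n_outer=config.n_outer,
                n_inner=config.n_inner,
                n_repeats=config.n_repeats,
                screening=screening,
                top_k=config.top_k,
                seed=derive_seed(seed, "nested", tp, label_cfg),
                impute_max_iter=config.impute_max_iter,
            )
            tab = res.metrics.copy()
            tab.insert(0, "configuration", label_cfg)
            tab.insert(0, "time_point", tp)
            tables.append(tab)
            results[f"nested_{tp}_{label_cfg}"] = {
                "delong": {k: dataclasses.asdict(v) for k, v in res.delong.items()},
                "calibration": res.calibration,
                "selected": res.screening_selected,
                "leakage_sentinel_ok": res.leakage_sentinel_ok,
            }
            if screening:
                final_selected = res.screening_selected
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / f"metrics_{tp}.csv", index=False
        )
        _stage(f"nested_{tp}")

        if config.run_shap:
            _shap_stage(config, data, labels, tp, final_selected, outdir, results)
            _stage(f"shap_{tp}")

    (outdir / "results.json").write_text(json.dumps(results, indent=1, default=float))
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["artifacts"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s artifacts", len(manifest["artifacts"]))
    return manifest


def _shap_stage(config, data, labels, tp, selected, outdir, results) -> None:
    """Fit the final-model learner on the full (preprocessed, screened)
    data and attribute its predictions with kernel SHAP."""
    from sklearn.ensemble import RandomForestClassifier

    seed = derive_seed(config.seed, "shap", tp)
    state = rf_impute_fit(
        data.predictors(), seed=derive_seed(seed, "impute"), max_iter=config.impute_max_iter
    )
    X = standardize_and_encode(state, data.predictors())
    if selected:
        groups = feature_groups(X.columns)
        X = X[[c for g in selected for c in groups.get(g, [])]]
    model = RandomForestClassifier(n_estimators=500, random_state=derive_seed(seed, "rf"), n_jobs=1)
    model.fit(X.to_numpy(), labels)

    rng = np.random.default_rng(derive_seed(seed, "bg"))
    bg_idx = _stratified_subsample(labels, min(config.shap_background, len(X)), rng)
    inst_idx = rng.choice(len(X), size=min(config.shap_instances, len(X)), replace=False)
    summary = kernel_shap(
        lambda M: model.predict_proba(M)[:, 1],
        X.iloc[bg_idx],
        X.iloc[inst_idx],
        n_coalitions=config.shap_coalitions,
        seed=derive_seed(seed, "coal"),
    )
    ranked = rank_and_sign(summary, k=config.top_k)
    ranked.to_csv(outdir / f"shap_ranking_{tp}.csv", index=False)
    plot_beeswarm(summary, k=config.top_k, path=outdir / f"shap_beeswarm_{tp}.svg",
                  title=f"Top predictors of optimization ({tp})")
    results[f"shap_{tp}"] = {
        "additivity_gap": summary.additivity_gap,
        "top": ranked.to_dict(orient="records"),
    }


def _stratified_subsample(labels, size, rng) -> np.ndarray:
    y = np.asarray(labels)
    idx = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        take = max(1, int(round(size * len(cls_idx) / len(y))))
        idx.append(rng.choice(cls_idx, size=min(take, len(cls_idx)), replace=False))
    return np.sort(np.concatenate(idx))
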