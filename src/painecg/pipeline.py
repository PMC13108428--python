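"""End-to-end orchestration: simulate -> segment -> extract -> train -> explain -> evaluate.

One :class:`RunConfig` (optionally loaded from YAML) drives a fully seeded
run; every stochastic stage derives its seed from the global seed, so a
given (config, seed) pair reproduces byte-identical metric files. External
recordings in the documented CSV layout can be ingested in place of
synthetic sessions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .cascade import CascadeModel, TrainConfig, fit_cascade, predict_cascade, save_model, standardize
from .errors import FormatError, ValidationError
from .evaluate import (
    auc_with_ci,
    bland_altman,
    classification_metrics,
    regression_metrics,
    stratified_metrics,
)
from .explain import (
    feature_correlations,
    gini_importance,
    global_surrogate,
    partial_dependence_ice,
    permutation_importance,
    tree_shapley,
)
from .features import build_feature_table
from .preprocess import TARGET_FS_HZ, resample_trace, segment_windows
from .synthdata import (
    AutonomicEffect,
    ProtocolSpec,
    SessionRecord,
    generate_session,
    read_session_csv,
)

__all__ = ["RunConfig", "run_experiment", "ingest_external", "build_study_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    n_sessions: int = 4
    fs_hz: float = 250.0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    effect: AutonomicEffect = field(default_factory=AutonomicEffect)
    ecg_noise_sd_mv: float = 0.02
    window_mode: str = "stimulus_aligned"
    label_reduction: str = "mean"
    train: TrainConfig = field(default_factory=TrainConfig)
    explain_rows: int = 12
    explain_background: int = 64
    permutation_repeats: int = 50
    pdp_top_features: int = 3
    out_dir: str = "run"
    plots: bool = False

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "protocol" in raw and isinstance(raw["protocol"], dict):
            p = dict(raw["protocol"])
            for key in ("rest_range_s", "level_temps_c", "covas_targets"):
                if key in p:
                    p[key] = tuple(p[key])
            raw["protocol"] = ProtocolSpec(**p)
        if "effect" in raw and isinstance(raw["effect"], dict):
            raw["effect"] = AutonomicEffect(**raw["effect"])
        if "train" in raw and isinstance(raw["train"], dict):
            raw["train"] = TrainConfig(**raw["train"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_study_table(config: RunConfig) -> pd.DataFrame:
    """Generate all sessions of a study and stack their feature tables.

    Each session gets its own derived seed; the table carries a ``session``
    column so grouped train/test splits can keep sessions intact.
    """
    tables = []
    for s in range(config.n_sessions):
        record = generate_session(
            protocol=config.protocol,
            effect=config.effect,
            fs_hz=config.fs_hz,
            seed=child_seed(config.seed, f"session-{s}"),
            ecg_noise_sd_mv=config.ecg_noise_sd_mv,
        )
        windows = segment_windows(
            record,
            mode=config.window_mode,  # type: ignore[arg-type]
            label_reduction=config.label_reduction,  # type: ignore[arg-type]
            session_id=f"s{s}",
        )
        table = build_feature_table(windows)
        table.insert(0, "session", f"s{s}")
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def _train_rows(full: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    return full.loc[~full.index.isin(test.index)]


def _json_dump(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, allow_nan=True)
        fh.write("\n")


def _clean_nan(obj: Any) -> Any:
    """JSON-friendly copy with NaN mapped to None (missing flags)."""
    if isinstance(obj, dict):
        return {k: _clean_nan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_nan(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes features.csv, model.joblib, metrics.json, importances.csv,
    shapley.csv, pdp_ice.json, surrogate_rules.txt, correlations.csv and a
    manifest.json recording the config, its hash and package version.
    Identical (config, seed) pairs produce byte-identical metrics.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/extract"
    try:
        table = build_study_table(config)
        table.to_csv(out / "features.csv", index=False)

        stage = "train"
        train_cfg = dataclasses.replace(config.train, seed=child_seed(config.seed, "train"))
        model, test = fit_cascade(table, train_cfg)
        save_model(model, out / "model.joblib")
        train = _train_rows(table, test)

        stage = "predict/evaluate"
        pred = predict_cascade(model, test)
        y_true = (test["covas_value"] > 0).astype(int).to_numpy()
        report = classification_metrics(y_true, pred["pain_label"].to_numpy())
        scores = pred["pain_probability"].to_numpy()
        auc_seed = child_seed(config.seed, "auc")
        report.auc_roc = auc_with_ci(y_true, scores, "roc", seed=auc_seed)
        report.auc_pr = auc_with_ci(y_true, scores, "pr", seed=auc_seed)
        metrics: dict[str, Any] = {"classification": report.as_dict()}

        pain_eval = (test["covas_value"] > 0).to_numpy() & (pred["pain_label"] == 1).to_numpy()
        if pain_eval.sum() >= 3:
            actual = test.loc[pain_eval, "covas_value"].to_numpy()
            predicted = pred.loc[pain_eval, "intensity"].to_numpy()
            metrics["regression"] = regression_metrics(actual, predicted).as_dict()
            metrics["bland_altman"] = bland_altman(actual, predicted).as_dict()
        strat = stratified_metrics(
            test["covas_value"].to_numpy(),
            pred["pain_label"].to_numpy(),
            pred["intensity"].to_numpy(),
        )
        metrics["strata"] = _clean_nan(strat.to_dict(orient="records"))

        stage = "explain"
        X_train, _ = standardize(train, scaler=model.scaler)
        X_train = X_train[model.selected_features]
        X_test, _ = standardize(test, scaler=model.scaler)
        X_test = X_test[model.selected_features]
        gini = gini_importance(model.classifier, model.selected_features)
        perm = permutation_importance(
            model.classifier,
            X_test,
            y_true,
            metric="accuracy",
            n_repeats=config.permutation_repeats,
            seed=child_seed(config.seed, "perm"),
        )
        imp = gini.as_frame().merge(
            perm.as_frame(), on="feature", suffixes=("_gini", "_permutation")
        )
        imp.to_csv(out / "importances.csv", index=False)

        bg_rng = np.random.default_rng(child_seed(config.seed, "background"))
        n_bg = min(config.explain_background, len(X_train))
        background = X_train.to_numpy()[
            bg_rng.choice(len(X_train), size=n_bg, replace=False)
        ]
        n_rows = min(config.explain_rows, len(X_test))
        shap_rows = X_test.to_numpy()[:n_rows]
        explanations = tree_shapley(
            model.classifier, shap_rows, background, feature_names=model.selected_features
        )
        tidy = [
            {
                "row": i,
                "feature": name,
                "value": float(shap_rows[i, j]),
                "phi": float(e.phi[j]),
            }
            for i, e in enumerate(explanations)
            for j, name in enumerate(model.selected_features)
        ]
        pd.DataFrame(tidy).to_csv(out / "shapley.csv", index=False)

        top = perm.ranking()[: config.pdp_top_features]
        pdp_payload = {}
        for feat in top:
            res = partial_dependence_ice(model.classifier, X_test, feat)
            pdp_payload[feat] = {
                "grid": res.grid.tolist(),
                "pd": res.pd_values.tolist(),
                "ice": res.ice.tolist(),
            }
        _json_dump(_clean_nan(pdp_payload), out / "pdp_ice.json")

        surrogate = global_surrogate(
            model.classifier, X_train, max_depth=5, seed=child_seed(config.seed, "surrogate")
        )
        (out / "surrogate_rules.txt").write_text(
            f"# fidelity (held-out agreement with the classifier): {surrogate.fidelity:.3f}\n"
            + "\n".join(surrogate.rules)
            + "\n"
        )
        metrics["surrogate_fidelity"] = surrogate.fidelity
        feature_correlations(table).to_csv(out / "correlations.csv")

        stage = "report"
        _json_dump(_clean_nan(metrics), out / "metrics.json")
        manifest = {
            "config": _clean_nan(config.to_dict()),
            "config_hash": config.config_hash(),
            "painecg_version": pkg_version("painecg"),
            "n_windows": int(len(table)),
            "n_test": int(len(test)),
            "selected_features": model.selected_features,
        }
        _json_dump(manifest, out / "manifest.json")

        if config.plots:
            from . import plots

            plots.run_plots(out, metrics, imp, pdp_payload)
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise
    return out


def ingest_external(path: str | Path, fs_target: float = TARGET_FS_HZ) -> list[SessionRecord]:
    """Load session CSVs (`t_s,ecg_mv,covas,stimulus_level`) from a directory or file.

    Sessions recorded at a different rate are resampled to ``fs_target``
    (logged); the CoVAS and stimulus channels are interpolated onto the new
    grid. Schema violations raise descriptive errors naming the column.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise FormatError(f"no session CSV files found under {path}")
    records = []
    for f in files:
        rec = read_session_csv(f)
        if rec.fs_hz != fs_target:
            logger.info("resampling %s from %g Hz to %g Hz", f.name, rec.fs_hz, fs_target)
            ecg = resample_trace(rec.ecg, rec.fs_hz, fs_target)
            t_old = rec.t_s
            t_new = np.arange(len(ecg)) / fs_target
            covas = np.interp(t_new, t_old, rec.covas)
            level = np.round(
                np.interp(t_new, t_old, rec.stimulus_level.astype(float))
            ).astype(int)
            rec = SessionRecord(
                ecg=ecg,
                fs_hz=fs_target,
                covas=np.clip(covas, 0.0, 100.0),
                stimulus_level=level,
                seed=rec.seed,
                truth=rec.truth,
                protocol=rec.protocol,
            )
        records.append(rec)
    return records
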