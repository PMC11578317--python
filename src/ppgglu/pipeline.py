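"""End-to-end orchestration: simulate -> extract -> train -> evaluate.

Everything here is deterministic given the seed; reports are plain dicts
(JSON-serializable, sorted keys when written) carrying the seed and a hash
of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import boosting, evaluation, fiducials, synthetic

__all__ = [
    "config_hash",
    "feature_matrix",
    "kfold_mard",
    "run_scenario",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration dict."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def feature_matrix(
    table: pd.DataFrame, use_p_features: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, column names) from a feature table.

    By default the personal covariates (P-features) enter the design matrix
    alongside the 11 waveform features; set ``use_p_features=False`` to
    train on waveform features alone.
    """
    cols = list(fiducials.FEATURE_NAMES)
    if use_p_features:
        cols += list(fiducials.P_FEATURE_NAMES)
    X = table[cols].to_numpy(dtype=float)
    y = table["y_glucose"].to_numpy(dtype=float)
    return X, y, cols


def kfold_mard(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: evaluation.ModelFactory,
    k: int = 5,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """K-fold cross-validated MARD plus the pooled out-of-fold predictions."""
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    pred = np.empty(n)
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = model_factory(i)
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
    report = evaluation.compute_metrics(y, pred)
    return report.mard, pred


def run_scenario(
    scenario: str = "nir_single",
    seed: int = 0,
    model: str = "gbdt",
    model_params: dict | None = None,
    test_fraction: float = 0.25,
    condition: bool = True,
    use_p_features: bool = True,
    link: synthetic.GlucoseLink | None = None,
) -> dict:
    """One-shot pipeline on a named scenario preset; returns the report dict.

    Simulates the cohort, extracts the feature table, fits the requested
    model on a seeded train split, and evaluates the held-out predictions
    with the accuracy metrics and the Clarke Error Grid.
    """
    config = {
        "scenario": scenario,
        "seed": seed,
        "model": model,
        "model_params": model_params or {},
        "test_fraction": test_fraction,
        "condition": condition,
        "use_p_features": use_p_features,
    }
    spec = synthetic.scenario_preset(scenario)
    entries = synthetic.simulate_cohort(spec, link=link, seed=seed)
    table = fiducials.build_feature_table(entries, condition=condition)
    X, y, cols = feature_matrix(table, use_p_features=use_p_features)

    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(y))))
    perm = rng.permutation(len(y))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    fitted = boosting.make_model(model, seed=seed, **(model_params or {}))
    fitted.fit(X[train_idx], y[train_idx])
    y_pred = fitted.predict(X[test_idx])

    metrics = evaluation.compute_metrics(y[test_idx], y_pred)
    clarke = evaluation.clarke_report(y[test_idx], y_pred)
    return {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "n_records": len(y),
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "feature_columns": cols,
        "metrics": {
            "mse": metrics.mse,
            "rmse": metrics.rmse,
            "mae": metrics.mae,
            "mard": metrics.mard,
            "r2": metrics.r2,
        },
        "clarke_percentages": clarke.percentages,
        "model": model,
        "_fitted_model": fitted,
        "_table": table,
        "_split": (train_idx.tolist(), test_idx.tolist()),
    }


def report_to_json(report: dict) -> str:
    """Serialize a pipeline report deterministically, dropping private keys."""
    public = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(public, sort_keys=True, indent=2)
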