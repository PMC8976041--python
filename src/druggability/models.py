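"""Tree-ensemble classifiers: gradient-boosted trees (XGB), random
forest (RF) and extremely randomized trees (ERT), with a common config,
deterministic single-threaded fitting, and an exhaustive grid search.

Default boosted-tree hyperparameters: 500 estimators, learning rate
(eta) 0.1, max depth 8, L2 (lambda) 1, L1 (alpha) 1. RF/ERT mirror the
500-estimator count and otherwise use library defaults.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from xgboost import XGBClassifier

ALGORITHMS = ("xgb", "rf", "ert")

_BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shared across the three tree ensembles.

    eta, reg_lambda and reg_alpha apply to the boosted-tree learner
    only; max_depth caps RF/ERT tree depth as well when set.
    """

    algorithm: str = "xgb"
    n_estimators: int = 500
    eta: float = 0.1
    max_depth: int = 8
    reg_lambda: float = 1.0
    reg_alpha: float = 1.0
    seed: int = 0
    n_jobs: int = 1  # single-threaded by default for bit-reproducibility
    extra: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.reg_lambda < 0 or self.reg_alpha < 0:
            raise ValueError("reg_lambda and reg_alpha must be >= 0")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)

    def as_dict(self) -> dict[str, Any]:
        d = {
            "algorithm": self.algorithm,
            "n_estimators": self.n_estimators,
            "eta": self.eta,
            "max_depth": self.max_depth,
            "reg_lambda": self.reg_lambda,
            "reg_alpha": self.reg_alpha,
            "seed": self.seed,
            "n_jobs": self.n_jobs,
        }
        d.update(dict(self.extra))
        return d


def make_estimator(config: ModelConfig):
    """Instantiate the scikit-learn-style estimator for a config."""
    extra = dict(config.extra)
    if config.algorithm == "xgb":
        return XGBClassifier(
            n_estimators=config.n_estimators,
            learning_rate=config.eta,
            max_depth=config.max_depth,
            reg_lambda=config.reg_lambda,
            reg_alpha=config.reg_alpha,
            random_state=config.seed,
            n_jobs=config.n_jobs,
            tree_method="hist",
            eval_metric="logloss",
            **extra,
        )
    cls = RandomForestClassifier if config.algorithm == "rf" else ExtraTreesClassifier
    return cls(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=config.n_jobs,
        **extra,
    )


@dataclass
class ModelBundle:
    """A fitted classifier plus the context needed to apply it safely."""

    config: ModelConfig
    estimator: Any
    feature_names: list[str]
    class_balance: dict[int, int]
    format_version: int = _BUNDLE_FORMAT_VERSION


def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(), list(X.columns)
    return np.asarray(X, dtype=float), None


def train(X, labels, config: ModelConfig | None = None) -> ModelBundle:
    """Fit a binary classifier; deterministic given config.seed with
    single-threaded fitting. Requires >= 2 samples per class and no NaNs."""
    config = config or ModelConfig()
    arr, names = _as_array(X)
    y = np.asarray(labels, dtype=int)
    if np.isnan(arr).any():
        raise ValueError("feature matrix contains NaN")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("need at least 2 samples per class to train")
    est = make_estimator(config)
    est.fit(arr, y)
    return ModelBundle(
        config=config,
        estimator=est,
        feature_names=names if names is not None else [f"f{i}" for i in range(arr.shape[1])],
        class_balance={0: int(counts[0]), 1: int(counts[1])},
    )


def _check_features(bundle: ModelBundle, X) -> np.ndarray:
    arr, names = _as_array(X)
    if names is not None and names != bundle.feature_names:
        missing = [n for n in bundle.feature_names if n not in names]
        extra = [n for n in names if n not in bundle.feature_names]
        raise ValueError(
            f"feature mismatch with training: missing {missing}, extra {extra}"
        )
    if arr.ndim != 2 or (arr.shape[0] > 0 and arr.shape[1] != len(bundle.feature_names)):
        raise ValueError(
            f"expected {len(bundle.feature_names)} features, got {arr.shape}"
        )
    return arr


def predict_proba(bundle: ModelBundle, X) -> np.ndarray:
    """Probability of the positive (druggable) class per sample."""
    arr = _check_features(bundle, X)
    if arr.shape[0] == 0:
        return np.zeros(0)
    return bundle.estimator.predict_proba(arr)[:, 1]


def predict(bundle: ModelBundle, X, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 where the positive-class probability >= threshold."""
    proba = predict_proba(bundle, X)
    return (proba >= threshold).astype(int)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist the bundle (binary artifact + JSON sidecar of its context)."""
    path = Path(path)
    joblib.dump(bundle, path)
    sidecar = {
        "format_version": bundle.format_version,
        "config": bundle.config.as_dict(),
        "feature_names": bundle.feature_names,
        "class_balance": {str(k): v for k, v in bundle.class_balance.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_bundle(path: str | Path) -> ModelBundle:
    bundle = joblib.load(path)
    if getattr(bundle, "format_version", None) != _BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"incompatible model bundle format (expected {_BUNDLE_FORMAT_VERSION})"
        )
    return bundle


def grid_search(
    X,
    labels,
    grid: dict[str, list[Any]],
    cv_folds: int = 10,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, list[tuple[dict[str, Any], float]]]:
    """Exhaustive stratified-CV grid search by mean accuracy.

    Every combination in the grid's Cartesian product is evaluated; ties
    are broken by earlier grid order. Returns the winning config and the
    full (params, mean accuracy) history in evaluation order.
    """
    from .evaluation import stratified_kfold  # local import to avoid a cycle

    if not grid:
        raise ValueError("empty grid")
    for key, vals in grid.items():
        if not vals:
            raise ValueError(f"empty value list for grid key {key!r}")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    base = base_config or ModelConfig()
    arr, _ = _as_array(X)
    y = np.asarray(labels, dtype=int)
    folds = stratified_kfold(y, k=cv_folds, seed=seed)

    keys = list(grid)
    history: list[tuple[dict[str, Any], float]] = []
    best: tuple[float, int, ModelConfig] | None = None
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        params = dict(zip(keys, combo))
        config = replace(base, **params).with_seed(seed)
        accs = []
        for test_idx in folds:
            mask = np.zeros(len(y), dtype=bool)
            mask[test_idx] = True
            bundle = train(arr[~mask], y[~mask], config)
            pred = predict(bundle, arr[mask])
            accs.append(float(np.mean(pred == y[mask])))
        mean_acc = float(np.mean(accs))
        history.append((params, mean_acc))
        if best is None or mean_acc > best[0]:
            best = (mean_acc, i, config)
    return best[2], history
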