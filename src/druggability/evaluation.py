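"""Stratified cross-validation and binary-classification metrics.

The metric suite reports accuracy, sensitivity, specificity, precision,
recall, F-measure, AUC and two Matthews-correlation variants:

``mcc``
    The standard Matthews correlation coefficient,
    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
``mcc_alt``
    An alternative formulation that circulates in the druggable-protein
    prediction literature: acc / sqrt((1 + err/P)(1 + err/N)) with
    err = fn + fp, P and N the class sizes. It equals 1 at perfect
    classification but is NOT algebraically the Matthews coefficient;
    both are reported so results are comparable either way.

Metrics whose denominator vanishes (e.g. an empty predicted class) are
reported as ``None`` rather than silently coerced to a number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = (
    "acc",
    "sn",
    "sp",
    "precision",
    "recall",
    "f_measure",
    "mcc",
    "mcc_alt",
    "auc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary prediction-outcome counts (positive = druggable)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def accuracy(cc: ConfusionCounts) -> float | None:
    """1 - (fn + fp) / (P + N)."""
    return _safe_div(cc.total - cc.fn - cc.fp, cc.total)


def sensitivity(cc: ConfusionCounts) -> float | None:
    """1 - fn / P (true positive rate)."""
    return _safe_div(cc.positives - cc.fn, cc.positives)


def specificity(cc: ConfusionCounts) -> float | None:
    """1 - fp / N (true negative rate)."""
    return _safe_div(cc.negatives - cc.fp, cc.negatives)


def precision(cc: ConfusionCounts) -> float | None:
    return _safe_div(cc.tp, cc.tp + cc.fp)


def recall(cc: ConfusionCounts) -> float | None:
    return _safe_div(cc.tp, cc.tp + cc.fn)


def f_measure(cc: ConfusionCounts) -> float | None:
    p, r = precision(cc), recall(cc)
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


def mcc(cc: ConfusionCounts) -> float | None:
    """Standard Matthews correlation coefficient."""
    den = math.sqrt(
        (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    if den == 0:
        return None
    return (cc.tp * cc.tn - cc.fp * cc.fn) / den


def mcc_alt(cc: ConfusionCounts) -> float | None:
    """Alternative MCC formulation: acc / sqrt((1 + err/P)(1 + err/N))."""
    if cc.positives == 0 or cc.negatives == 0 or cc.total == 0:
        return None
    err = cc.fn + cc.fp
    num = 1 - err / cc.total
    den = math.sqrt((1 + err / cc.positives) * (1 + err / cc.negatives))
    return num / den


def auc(y_true, proba) -> float | None:
    """Rank-based area under the ROC curve (ties by mid-ranks)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(set(np.unique(y_true))) < 2:
        return None
    return float(roc_auc_score(y_true, np.asarray(proba, dtype=float)))


def metric_suite(cc: ConfusionCounts, y_true=None, proba=None) -> dict[str, float | None]:
    out: dict[str, float | None] = {
        "acc": accuracy(cc),
        "sn": sensitivity(cc),
        "sp": specificity(cc),
        "precision": precision(cc),
        "recall": recall(cc),
        "f_measure": f_measure(cc),
        "mcc": mcc(cc),
        "mcc_alt": mcc_alt(cc),
        "auc": auc(y_true, proba) if y_true is not None and proba is not None else None,
    }
    return out


def stratified_kfold(labels, k: int = 10, seed: int = 42) -> list[np.ndarray]:
    """k disjoint index folds with near-proportional class counts
    (per-fold class counts within 1 of proportionality), shuffled
    deterministically by the seed."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in splitter.split(np.zeros(len(y)), y)]


@dataclass
class MetricsReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: list[dict[str, float | None]]
    fold_assignments: list[list[int]]
    seed: int
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, dict[str, float | None]]:
        """mean and sd per metric over folds where the metric is defined."""
        out: dict[str, dict[str, float | None]] = {}
        for m in METRIC_NAMES:
            vals = [f[m] for f in self.per_fold if f.get(m) is not None]
            if vals:
                out[m] = {
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            else:
                out[m] = {"mean": None, "sd": None}
        return out

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "config": self.config,
            "per_fold": self.per_fold,
            "summary": self.summary,
            "fold_assignments": self.fold_assignments,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))

    def to_csv(self, path: str | Path, classifier: str = "", descriptor: str = "") -> None:
        """Flat benchmark-style CSV: one row per fold plus a summary row
        (columns: classifier, feature descriptor, Acc, Sn, Sp, F-measure,
        MCC)."""
        rows = []
        for i, f in enumerate(self.per_fold, start=1):
            rows.append(_report_row(classifier, descriptor, f"fold{i}", f))
        means = {m: self.summary[m]["mean"] for m in METRIC_NAMES}
        rows.append(_report_row(classifier, descriptor, "mean", means))
        pd.DataFrame(rows).to_csv(path, index=False)


def _report_row(classifier: str, descriptor: str, fold: str, m: dict) -> dict:
    def pct(x):
        return None if x is None else round(100 * x, 2)

    return {
        "classifier": classifier,
        "feature_descriptor": descriptor,
        "fold": fold,
        "Acc(%)": pct(m.get("acc")),
        "Sn(%)": pct(m.get("sn")),
        "Sp(%)": pct(m.get("sp")),
        "F-measure(%)": pct(m.get("f_measure")),
        "MCC": None if m.get("mcc") is None else round(m["mcc"], 4),
    }


def cross_validate(
    data,
    encoder_specs,
    model_config=None,
    selection_ks: dict[str, int] | None = None,
    selection_scope: str = "per_fold",
    selection_step: int = 1,
    k: int = 10,
    seed: int = 42,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full method.

    Sequences are encoded once (encoding is per-sequence and label-free,
    so it cannot leak fold information). When ``selection_ks`` maps
    encoder names to retained feature counts, recursive elimination runs
    either inside each fold on the training portion only
    (``selection_scope="per_fold"``, leak-free default) or once on the
    whole dataset (``"global"``, the optimistic protocol some published
    benchmarks appear to use). Each fold then trains on the remaining
    nine-tenths and is scored on the held-out tenth.
    """
    from .encoders import FeatureMatrix, encode_dataset
    from .feat_select import select_superset
    from .models import ModelConfig, predict_proba, train

    if selection_scope not in ("per_fold", "global"):
        raise ValueError("selection_scope must be 'per_fold' or 'global'")
    model_config = model_config or ModelConfig()
    y = np.asarray(data.labels, dtype=int)

    blocks = {spec.name: encode_dataset(data, [spec]) for spec in encoder_specs}

    def concat(block_map) -> FeatureMatrix:
        X = pd.concat([fm.X for fm in block_map.values()], axis=1)
        return FeatureMatrix(X=X, labels=y)

    if selection_ks:
        unknown = set(selection_ks) - set(blocks)
        if unknown:
            raise ValueError(f"selection ks for unknown encoders: {sorted(unknown)}")

    folds = stratified_kfold(y, k=k, seed=seed)

    if selection_ks and selection_scope == "global":
        per_encoder = {
            name: (fm, selection_ks.get(name, fm.shape[1]))
            for name, fm in blocks.items()
        }
        full, _ = select_superset(
            per_encoder, seed=seed, step=selection_step, config=model_config
        )
    else:
        full = concat(blocks)

    per_fold: list[dict[str, float | None]] = []
    for fold_idx, test_idx in enumerate(folds):
        try:
            mask = np.zeros(len(y), dtype=bool)
            mask[test_idx] = True
            if selection_ks and selection_scope == "per_fold":
                per_encoder = {
                    name: (
                        FeatureMatrix(
                            X=fm.X[~mask].reset_index(drop=True), labels=y[~mask]
                        ),
                        selection_ks.get(name, fm.shape[1]),
                    )
                    for name, fm in blocks.items()
                }
                train_fm, results = select_superset(
                    per_encoder, seed=seed, step=selection_step, config=model_config
                )
                cols = list(train_fm.X.columns)
                X_train, y_train = train_fm.X, y[~mask]
                X_test = concat(blocks).X.loc[mask, cols]
            else:
                X_train, y_train = full.X[~mask], y[~mask]
                X_test = full.X[mask]
            bundle = train(X_train, y_train, model_config.with_seed(seed))
            proba = predict_proba(bundle, X_test)
            pred = (proba >= 0.5).astype(int)
            cc = confusion(y[mask], pred)
            per_fold.append(metric_suite(cc, y_true=y[mask], proba=proba))
        except ValueError as exc:
            raise ValueError(f"fold {fold_idx + 1}: {exc}") from exc

    return MetricsReport(
        per_fold=per_fold,
        fold_assignments=[sorted(int(i) for i in f) for f in folds],
        seed=seed,
        config={
            "model": model_config.as_dict(),
            "encoders": [spec.name for spec in encoder_specs],
            "selection_ks": selection_ks,
            "selection_scope": selection_scope if selection_ks else None,
            "selection_step": selection_step if selection_ks else None,
            "cv_folds": k,
        },
    )
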