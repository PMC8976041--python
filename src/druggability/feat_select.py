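"""Boosted-tree recursive feature elimination (XGB-RFE).

A gradient-boosted tree model is fitted on the labeled feature matrix,
each feature is scored by its total split gain summed over all trees,
and the lowest-scoring features are dropped; fit-score-drop repeats
until the requested number of features remains. Selection within each
encoder block followed by concatenation yields the optimized "superset"
(defaults: 17 grouped-dipeptide, 73 reduced-alphabet, 36 segmented-PseAAC
features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import FeatureMatrix
from .models import ModelConfig, make_estimator

#: Per-encoder retained feature counts for the optimized superset.
DEFAULT_SUPERSET_KS: dict[str, int] = {"gdpc": 17, "raaa": 73, "s_pseaac": 36}


@dataclass
class SelectionResult:
    """Outcome of a recursive-elimination run.

    ranking
        All original features, most to least important: the survivors in
        final-fit importance order, then eliminated features in reverse
        drop order.
    scores
        Importance values aligned to ``ranking`` (survivors carry their
        final-fit gain; eliminated features the gain from the fit that
        dropped them), non-increasing within each segment.
    selected
        The retained feature names, in ranking order.
    history
        Per-iteration (n_features_remaining_before, dropped_names).
    """

    ranking: list[str]
    scores: list[float]
    selected: list[str]
    history: list[tuple[int, list[str]]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ranking": self.ranking,
                    "scores": self.scores,
                    "selected": self.selected,
                    "history": [
                        {"n_features": n, "dropped": d} for n, d in self.history
                    ],
                },
                indent=2,
            )
        )


def _check_two_classes(labels: np.ndarray) -> None:
    counts = np.bincount(labels, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("need at least 2 samples per class")


def importance_scores(
    fm: FeatureMatrix, seed: int = 0, config: ModelConfig | None = None
) -> pd.Series:
    """Total split-gain importance per feature from one boosted-tree fit.

    Features never chosen for any split score exactly 0. Scores are
    returned in the matrix's column order.
    """
    from dataclasses import replace

    _check_two_classes(fm.labels)
    config = (config or ModelConfig(algorithm="xgb")).with_seed(seed)
    if config.algorithm != "xgb":
        config = replace(config, algorithm="xgb")  # gain scores need the booster
    est = make_estimator(config)
    est.fit(fm.X.to_numpy(), fm.labels)
    gain = est.get_booster().get_score(importance_type="total_gain")
    # booster reports features as f{column index}
    scores = np.zeros(fm.shape[1])
    for key, val in gain.items():
        scores[int(key[1:])] = val
    return pd.Series(scores, index=fm.feature_names, name="total_gain")


def xgb_rfe(
    fm: FeatureMatrix,
    k: int,
    step: int = 1,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> SelectionResult:
    """Recursively eliminate the lowest-gain features until k remain.

    Each iteration refits on the surviving features and drops the
    ``step`` lowest-scoring ones (clamped so exactly k survive); score
    ties are broken by dropping the larger column index first. The run
    is deterministic given the seed.
    """
    n_features = fm.shape[1]
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} outside [1, {n_features}]")
    if step < 1:
        raise ValueError("step must be >= 1")

    surviving = list(fm.X.columns)
    col_index = {name: i for i, name in enumerate(fm.X.columns)}
    history: list[tuple[int, list[str]]] = []
    eliminated: list[tuple[str, float]] = []  # in drop order

    scores = importance_scores(fm, seed=seed, config=config)
    while len(surviving) > k:
        n_drop = min(step, len(surviving) - k)
        # ascending score; ties -> larger original column index drops first
        order = sorted(
            surviving, key=lambda name: (scores[name], -col_index[name])
        )
        dropped = order[:n_drop]
        history.append((len(surviving), dropped))
        eliminated.extend((name, float(scores[name])) for name in dropped)
        dropped_set = set(dropped)
        surviving = [name for name in surviving if name not in dropped_set]
        sub = FeatureMatrix(X=fm.X[surviving], labels=fm.labels)
        scores = importance_scores(sub, seed=seed, config=config)

    kept_order = sorted(
        surviving, key=lambda name: (-scores[name], col_index[name])
    )
    ranking = kept_order + [name for name, _ in reversed(eliminated)]
    rank_scores = [float(scores[name]) for name in kept_order] + [
        s for _, s in reversed(eliminated)
    ]
    return SelectionResult(
        ranking=ranking,
        scores=rank_scores,
        selected=kept_order,
        history=history,
    )


def select_superset(
    per_encoder: dict[str, tuple[FeatureMatrix, int]],
    seed: int = 0,
    step: int = 1,
    config: ModelConfig | None = None,
) -> tuple[FeatureMatrix, dict[str, SelectionResult]]:
    """Run RFE per encoder block and concatenate the selected columns.

    ``per_encoder`` maps encoder name to (feature matrix, k); blocks are
    concatenated in the mapping's order (canonically GDPC, RAAA,
    S-PseAAC). All blocks must share sample order and labels.
    """
    if not per_encoder:
        raise ValueError("no encoder blocks given")
    mats = [fm for fm, _ in per_encoder.values()]
    ref = mats[0].labels
    for fm in mats[1:]:
        if len(fm.labels) != len(ref) or not np.array_equal(fm.labels, ref):
            raise ValueError("encoder blocks disagree on sample order/labels")
    results: dict[str, SelectionResult] = {}
    blocks: list[pd.DataFrame] = []
    for name, (fm, k) in per_encoder.items():
        res = xgb_rfe(fm, k=k, step=step, seed=seed, config=config)
        results[name] = res
        # keep original column order within the block
        keep = [c for c in fm.X.columns if c in set(res.selected)]
        blocks.append(fm.X[keep])
    combined = FeatureMatrix(X=pd.concat(blocks, axis=1), labels=ref.copy())
    return combined, results
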