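"""Synthetic labeled protein datasets with controllable class separation.

Negatives are drawn i.i.d. from a background distribution over the 20
canonical residues (uniform by default); positives from the same
distribution with the probabilities of an enriched residue set
(aromatic {W, Y, F} by default) multiplied by (1 + delta) and
renormalized. delta = 0 makes the classes exchangeable — an exact null.
Aromatic enrichment is used because all three encoders can see it
(the grouped-dipeptide aromatic class, the reduced-alphabet clusters
containing FYW, and the composition part of PseAAC).

This generator validates machinery, not biology: it makes no attempt to
mimic real druggable-protein sequence statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabets import CANONICAL_RESIDUES
from .seq_io import LabeledDataset, ProteinRecord, write_fasta


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 250
    n_neg: int = 250
    len_min: int = 50
    len_max: int = 300
    delta: float = 5.0
    enriched_set: frozenset[str] = frozenset("WYF")
    seed: int = 0
    #: optional background residue probabilities (length 20, canonical
    #: order); None = uniform
    background: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 1 <= self.len_min <= self.len_max:
            raise ValueError("need 1 <= len_min <= len_max")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not self.enriched_set <= set(CANONICAL_RESIDUES):
            raise ValueError("enriched_set must be canonical residues")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 probabilities summing to 1")

    def as_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "len_min": self.len_min,
            "len_max": self.len_max,
            "delta": self.delta,
            "enriched_set": "".join(sorted(self.enriched_set)),
            "seed": self.seed,
            "background": list(self.background) if self.background else None,
        }


def _class_probs(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    bg = (
        np.asarray(config.background, dtype=float)
        if config.background is not None
        else np.full(20, 1 / 20)
    )
    enriched_mask = np.array([r in config.enriched_set for r in CANONICAL_RESIDUES])
    pos = bg * np.where(enriched_mask, 1 + config.delta, 1.0)
    return pos / pos.sum(), bg


def generate(config: SyntheticConfig) -> LabeledDataset:
    """Draw a fully seeded labeled dataset; positives first, labels
    [1]*n_pos + [0]*n_neg, ids unique."""
    rng = np.random.default_rng(config.seed)
    pos_p, neg_p = _class_probs(config)
    residues = np.array(list(CANONICAL_RESIDUES))

    def draw(n: int, probs: np.ndarray, prefix: str) -> list[ProteinRecord]:
        recs = []
        for i in range(n):
            L = int(rng.integers(config.len_min, config.len_max + 1))
            seq = "".join(rng.choice(residues, size=L, p=probs))
            recs.append(ProteinRecord(id=f"{prefix}{i + 1}", sequence=seq))
        return recs

    pos = draw(config.n_pos, pos_p, "pos")
    neg = draw(config.n_neg, neg_p, "neg")
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    return LabeledDataset(records=pos + neg, labels=labels)


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize pos.fasta / neg.fasta plus a manifest JSON echoing the
    config and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = generate(config)
    pos = [r for r, y in zip(data.records, data.labels) if y == 1]
    neg = [r for r, y in zip(data.records, data.labels) if y == 0]
    paths = {
        "pos": out_dir / "pos.fasta",
        "neg": out_dir / "neg.fasta",
        "manifest": out_dir / "manifest.json",
    }
    write_fasta(pos, paths["pos"])
    write_fasta(neg, paths["neg"])
    paths["manifest"].write_text(json.dumps(config.as_dict(), indent=2))
    return paths


def planted_features(
    n: int = 400,
    n_informative: int = 10,
    n_noise: int = 90,
    shift: float = 1.0,
    seed: int = 0,
):
    """Tabular benchmark for the selection machinery: balanced labels,
    ``n_informative`` Gaussian features whose mean is shifted by
    ``shift`` in the positive class, and ``n_noise`` pure-noise features,
    all unit variance. Returns (FeatureMatrix, planted feature names)."""
    import pandas as pd

    from .encoders import FeatureMatrix

    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    informative = rng.normal(0, 1, (n, n_informative)) + shift * y[:, None]
    noise = rng.normal(0, 1, (n, n_noise))
    names = [f"signal_{i + 1}" for i in range(n_informative)] + [
        f"noise_{i + 1}" for i in range(n_noise)
    ]
    X = pd.DataFrame(np.hstack([informative, noise]), columns=names)
    # shuffle sample order so class blocks are not contiguous
    perm = rng.permutation(n)
    fm = FeatureMatrix(X=X.iloc[perm].reset_index(drop=True), labels=y[perm])
    return fm, names[:n_informative]
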