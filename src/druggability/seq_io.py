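"""Protein sequence and label I/O.

Reads FASTA files into :class:`ProteinRecord` lists, sanitizes records
against the canonical 20-letter alphabet, and assembles two-FASTA
(positive/negative) inputs into a :class:`LabeledDataset`. Feature
matrices travel as CSV with a header row of feature names and the label
in a final ``label`` column; reports as JSON.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabets import CANONICAL_RESIDUES

_CANONICAL = frozenset(CANONICAL_RESIDUES)

SanitizePolicy = Literal["strict", "skip"]


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SanitizationError(ValueError):
    """A record violates the canonical-alphabet contract under strict policy."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class LabeledDataset:
    """Ordered records with an aligned binary label vector
    (1 = druggable, 0 = non-druggable)."""

    records: list[ProteinRecord]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file; ids are headers truncated at first whitespace.

    Wrapped sequence lines are joined; blank lines ignored. A sequence
    line appearing before any ``>`` header raises :class:`FastaParseError`
    naming the line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
        break
    records = []
    for header, seq in SimpleFastaParser(io.StringIO(text)):
        rec_id = header.split()[0] if header.split() else header
        if not rec_id:
            raise FastaParseError(f"{path}: empty FASTA header")
        records.append(ProteinRecord(id=rec_id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass
class SanitationLog:
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    modified: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"dropped": self.dropped, "modified": self.modified}


def sanitize(
    records: Iterable[ProteinRecord], policy: SanitizePolicy = "skip"
) -> tuple[list[ProteinRecord], SanitationLog]:
    """Force records onto the canonical uppercase 20-letter alphabet.

    Case is folded and ``*`` stop characters stripped under either policy
    (logged as modifications). Records still containing non-canonical
    residues (B, J, O, U, X, Z, gaps, ...) are then dropped and logged
    under ``skip``, or raise :class:`SanitizationError` under ``strict``.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown sanitize policy {policy!r}")
    log = SanitationLog()
    out: list[ProteinRecord] = []
    for rec in records:
        seq = rec.sequence.upper()
        if seq != rec.sequence:
            log.modified.append((rec.id, "case-folded to uppercase"))
        if "*" in seq:
            seq = seq.replace("*", "")
            log.modified.append((rec.id, "stripped '*' stop characters"))
        bad = sorted(set(seq) - _CANONICAL)
        if bad:
            if policy == "strict":
                raise SanitizationError(
                    f"record {rec.id!r}: non-canonical residue(s) {''.join(bad)}"
                )
            log.dropped.append((rec.id, f"non-canonical residue(s) {''.join(bad)}"))
            continue
        if not seq:
            if policy == "strict":
                raise SanitizationError(f"record {rec.id!r}: empty after sanitization")
            log.dropped.append((rec.id, "empty after sanitization"))
            continue
        out.append(ProteinRecord(id=rec.id, sequence=seq))
    return out, log


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    policy: SanitizePolicy = "skip",
) -> tuple[LabeledDataset, SanitationLog]:
    """Load positives (label 1) and negatives (label 0) from two FASTA
    files, sanitized; order within each file is preserved, positives first."""
    pos, log_p = sanitize(read_fasta(pos_path), policy)
    neg, log_n = sanitize(read_fasta(neg_path), policy)
    log = SanitationLog(
        dropped=log_p.dropped + log_n.dropped,
        modified=log_p.modified + log_n.modified,
    )
    if not pos:
        raise ValueError(f"positive class empty after sanitization ({pos_path})")
    if not neg:
        raise ValueError(f"negative class empty after sanitization ({neg_path})")
    from collections import Counter

    counts = Counter(r.id for r in pos + neg)
    dupes = sorted(i for i, c in counts.items() if c > 1)
    if dupes:
        raise ValueError(f"duplicate record ids across classes: {dupes}")
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return LabeledDataset(records=pos + neg, labels=labels), log


def write_feature_csv(X: pd.DataFrame, labels: np.ndarray, path: str | Path) -> None:
    """Feature matrix to CSV: named feature columns plus a final ``label``."""
    out = X.copy()
    out["label"] = np.asarray(labels, dtype=int)
    out.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    labels = df["label"].to_numpy(dtype=int)
    return df.drop(columns=["label"]), labels
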