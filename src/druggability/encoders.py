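"""Sequence feature encoders for druggable-protein prediction.

Implemented descriptors:

``aac``
    Amino acid composition: the 20 residue frequencies.
``gdpc``
    Grouped dipeptide composition over five physicochemical classes
    (aromatic, positive, aliphatic, uncharged, negative): 25 features,
    f(m, n) = T_mn / (T - 1) with T_mn the count of adjacent ordered
    residue pairs falling in groups (m, n) and T the sequence length.
``raaa``
    Reduced amino acid alphabet statistics over the Etchebest clusterings
    C(5), C(8), C(9), C(11), C(13): per scheme, the k cluster frequencies
    followed by the k^2 cluster-dipeptide frequencies; 506 features total.
``pseaac``
    Type-1 pseudo amino acid composition: the 20 AAC frequencies extended
    with lam sequence-order correlation factors theta_j, all normalized by
    1 + w * sum(theta). theta_j averages the squared property differences
    of residues j positions apart over standardized hydrophobicity,
    hydrophilicity and side-chain mass.
``s_pseaac``
    Segmented PseAAC: the sequence is cut into n_seg contiguous
    near-equal segments and PseAAC computed per segment, concatenated,
    capturing local composition the global descriptor averages away.

All encoders return a :class:`FeatureVector` with stable, unique names,
and are deterministic functions of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    import pandas as pd

from .alphabets import (
    CANONICAL_RESIDUES,
    GDPC_SCHEME,
    RAAA_SCHEMES,
    GroupScheme,
    standardized_properties,
)

_RES_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


@dataclass(frozen=True)
class FeatureVector:
    """Named numeric feature vector; names are unique and aligned to values."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names not unique")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PseAACParams:
    """Pseudo amino acid composition parameters.

    lam
        Number of sequence-order correlation tiers (lag distances); 0
        collapses PseAAC to plain AAC.
    w
        Weight of the correlation block relative to composition.
    properties
        3 x 20 standardized property table (rows: hydrophobicity,
        hydrophilicity, side-chain mass; columns as the canonical
        alphabet). Each row must have mean 0 and population standard
        deviation 1 to within 1e-9.
    """

    lam: int = 5
    w: float = 0.05
    properties: np.ndarray = field(default_factory=standardized_properties)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        props = np.asarray(self.properties, dtype=float)
        if props.shape != (3, 20):
            raise ValueError("properties must be a 3 x 20 table")
        if not (
            np.allclose(props.mean(axis=1), 0.0, atol=1e-9)
            and np.allclose(props.std(axis=1), 1.0, atol=1e-9)
        ):
            raise ValueError("property rows must be standardized (mean 0, pop. sd 1)")
        object.__setattr__(self, "properties", props)


@dataclass(frozen=True)
class SegmentationScheme:
    """Cut a length-L sequence into n_seg contiguous near-equal segments.

    Segment k (1-based) covers 1-based inclusive positions
    floor((k-1) * L / n_seg) + 1 .. floor(k * L / n_seg).
    """

    n_seg: int = 2

    def __post_init__(self) -> None:
        if self.n_seg < 1:
            raise ValueError("n_seg must be >= 1")

    def segments(self, seq: str) -> list[str]:
        L = len(seq)
        if L < self.n_seg:
            raise ValueError(
                f"sequence of length {L} cannot be cut into {self.n_seg} segments"
            )
        bounds = [(k * L) // self.n_seg for k in range(self.n_seg + 1)]
        return [seq[bounds[k] : bounds[k + 1]] for k in range(self.n_seg)]


def _check_sequence(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence length {len(seq)} < required {min_len}")
    bad = set(seq) - set(CANONICAL_RESIDUES)
    if bad:
        raise ValueError(f"non-canonical residue(s) {''.join(sorted(bad))}")


def aac(seq: str) -> FeatureVector:
    """Amino acid composition: residue counts divided by length; sums to 1."""
    _check_sequence(seq, 1)
    counts = np.zeros(20)
    for r in seq:
        counts[_RES_INDEX[r]] += 1
    return FeatureVector(
        names=tuple(f"AAC|{r}" for r in CANONICAL_RESIDUES),
        values=counts / len(seq),
    )


def reduce_sequence(seq: str, scheme: GroupScheme) -> list[int]:
    """Recode each residue as the 1-based index of its cluster in *scheme*."""
    _check_sequence(seq, 1)
    return [scheme.index_of(r) + 1 for r in seq]


def _grouped_dipeptide(seq: str, scheme: GroupScheme) -> np.ndarray:
    """k x k adjacent-pair frequencies over a scheme's groups, row-major
    (first-residue group varies slowest); total mass 1 for len >= 2."""
    k = scheme.n_groups
    counts = np.zeros((k, k))
    for a, b in zip(seq, seq[1:]):
        counts[scheme.index_of(a), scheme.index_of(b)] += 1
    return counts.ravel() / (len(seq) - 1)


def gdpc(seq: str) -> FeatureVector:
    """Grouped dipeptide composition over the five physicochemical classes."""
    _check_sequence(seq, 1)
    if len(seq) < 2:
        raise ValueError("no dipeptides: sequence length < 2")
    names = tuple(
        f"GDPC|{m}>{n}"
        for m in GDPC_SCHEME.group_names
        for n in GDPC_SCHEME.group_names
    )
    return FeatureVector(names=names, values=_grouped_dipeptide(seq, GDPC_SCHEME))


def _grouped_composition(seq: str, scheme: GroupScheme) -> np.ndarray:
    counts = np.zeros(scheme.n_groups)
    for r in seq:
        counts[scheme.index_of(r)] += 1
    return counts / len(seq)


def raaa(seq: str) -> FeatureVector:
    """Reduced-alphabet composition + dipeptide composition for each of the
    five Etchebest schemes, concatenated in ascending cluster count:
    sum of k + k^2 over k in {5, 8, 9, 11, 13} = 506 features."""
    _check_sequence(seq, 2)
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for k in sorted(RAAA_SCHEMES):
        scheme = RAAA_SCHEMES[k]
        names += [f"RAAA|C{k}|comp|{i + 1}" for i in range(k)]
        blocks.append(_grouped_composition(seq, scheme))
        names += [f"RAAA|C{k}|dp|{i + 1}>{j + 1}" for i in range(k) for j in range(k)]
        blocks.append(_grouped_dipeptide(seq, scheme))
    return FeatureVector(names=tuple(names), values=np.concatenate(blocks))


@dataclass
class FeatureMatrix:
    """Samples x named features with an aligned binary label vector."""

    X: "pd.DataFrame"
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.X) != len(self.labels):
            raise ValueError("feature matrix and labels have different lengths")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def theta_correlations(seq: str, params: PseAACParams) -> np.ndarray:
    """Sequence-order correlation factors theta_1 .. theta_lam.

    theta_j = mean over positions i of Theta(R_i, R_{i+j}), where
    Theta(a, b) averages the squared differences of the three
    standardized properties. Requires L > lam.
    """
    _check_sequence(seq, 1)
    L = len(seq)
    if L <= params.lam:
        raise ValueError(f"sequence shorter than lambda+1 (L={L}, lam={params.lam})")
    if params.lam == 0:
        return np.zeros(0)
    idx = np.array([_RES_INDEX[r] for r in seq])
    props = params.properties[:, idx]  # 3 x L
    thetas = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        diff = props[:, :-j] - props[:, j:]
        thetas[j - 1] = np.mean((diff**2).mean(axis=0))
    return thetas


def pseaac(seq: str, params: PseAACParams | None = None, _prefix: str = "PseAAC") -> FeatureVector:
    """Type-1 pseudo amino acid composition of length 20 + lam; sums to 1."""
    params = params or PseAACParams()
    thetas = theta_correlations(seq, params)
    f = aac(seq).values
    denom = 1.0 + params.w * thetas.sum()
    values = np.concatenate([f / denom, params.w * thetas / denom])
    names = tuple(
        [f"{_prefix}|aac|{r}" for r in CANONICAL_RESIDUES]
        + [f"{_prefix}|lam{j}" for j in range(1, params.lam + 1)]
    )
    return FeatureVector(names=names, values=values)


def s_pseaac(
    seq: str,
    params: PseAACParams | None = None,
    seg: SegmentationScheme | None = None,
) -> FeatureVector:
    """Segmented PseAAC: per-segment PseAAC vectors concatenated in order;
    n_seg * (20 + lam) features, each segment block summing to 1."""
    params = params or PseAACParams()
    seg = seg or SegmentationScheme()
    _check_sequence(seq, 1)
    pieces = seg.segments(seq)
    for k, piece in enumerate(pieces, start=1):
        if len(piece) <= params.lam:
            raise ValueError(
                f"segment {k} has length {len(piece)} <= lambda ({params.lam})"
            )
    parts = [
        pseaac(piece, params, _prefix=f"SPseAAC|seg{k}")
        for k, piece in enumerate(pieces, start=1)
    ]
    return FeatureVector(
        names=tuple(n for p in parts for n in p.names),
        values=np.concatenate([p.values for p in parts]),
    )


@dataclass(frozen=True)
class EncoderSpec:
    """A named encoder plus its parameters, as listed in a run config.

    name: one of {"aac", "gdpc", "raaa", "pseaac", "s_pseaac"};
    params: keyword arguments forwarded to the encoder (e.g. lam, w,
    n_seg). The canonical "All features" order is GDPC, RAAA, S-PseAAC.
    """

    name: str
    params: tuple[tuple[str, object], ...] = ()

    @classmethod
    def make(cls, name: str, **params) -> "EncoderSpec":
        if name not in _ENCODER_BUILDERS:
            raise ValueError(
                f"unknown encoder {name!r}; known: {sorted(_ENCODER_BUILDERS)}"
            )
        return cls(name=name, params=tuple(sorted(params.items())))

    def encode(self, seq: str) -> FeatureVector:
        return _ENCODER_BUILDERS[self.name](seq, dict(self.params))


def _build_aac(seq, params):
    return aac(seq)


def _build_gdpc(seq, params):
    return gdpc(seq)


def _build_raaa(seq, params):
    return raaa(seq)


def _pse_params(params) -> PseAACParams:
    kwargs = {k: params[k] for k in ("lam", "w") if k in params}
    return PseAACParams(**kwargs)


def _build_pseaac(seq, params):
    return pseaac(seq, _pse_params(params))


def _build_s_pseaac(seq, params):
    seg = SegmentationScheme(n_seg=int(params.get("n_seg", 2)))
    return s_pseaac(seq, _pse_params(params), seg)


_ENCODER_BUILDERS = {
    "aac": _build_aac,
    "gdpc": _build_gdpc,
    "raaa": _build_raaa,
    "pseaac": _build_pseaac,
    "s_pseaac": _build_s_pseaac,
}

#: "All features" concatenation order: GDPC, RAAA, S-PseAAC.
DEFAULT_ENCODERS: tuple[str, ...] = ("gdpc", "raaa", "s_pseaac")


def encode_dataset(data, specs: "list[EncoderSpec]") -> FeatureMatrix:
    """Encode every record with every spec and column-concatenate the
    blocks in the given order; feature names stay globally unique via the
    encoder prefixes. Any per-sequence failure is re-raised with the
    record id attached."""
    import pandas as pd

    if not specs:
        raise ValueError("no encoders given")
    rows: list[np.ndarray] = []
    names: tuple[str, ...] | None = None
    for rec in data.records:
        vecs = []
        for spec in specs:
            try:
                vecs.append(spec.encode(rec.sequence))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: encoder {spec.name}: {exc}") from exc
        row_names = tuple(n for v in vecs for n in v.names)
        if names is None:
            names = row_names
        elif row_names != names:
            raise ValueError("inconsistent feature names across records")
        rows.append(np.concatenate([v.values for v in vecs]))
    X = pd.DataFrame(np.vstack(rows), columns=list(names))
    return FeatureMatrix(X=X, labels=data.labels)
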