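"""Canonical residue alphabet, physicochemical group schemes and the
standardized property table used by the pseudo amino acid composition.

Two families of schemes live here:

* the five-class physicochemical grouping behind the grouped dipeptide
  composition (aromatic / positive / aliphatic / uncharged / negative);
* the Etchebest-style reduced amino acid alphabets C(5), C(8), C(9),
  C(11), C(13), where C(k) recodes the 20 residues into k clusters.

Every scheme is validated at import time to be a partition of the
canonical 20-letter alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 canonical amino acids, alphabetical one-letter codes.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class GroupScheme:
    """An ordered partition of the 20 canonical residues into named groups."""

    name: str
    group_names: tuple[str, ...]
    groups: tuple[frozenset[str], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.groups):
            raise ValueError(f"{self.name}: group names/sets length mismatch")
        seen: set[str] = set()
        for g in self.groups:
            if g & seen:
                raise ValueError(
                    f"{self.name}: residues {sorted(g & seen)} appear in more than one group"
                )
            seen |= g
        if seen != _CANONICAL_SET:
            missing = sorted(_CANONICAL_SET - seen)
            extra = sorted(seen - _CANONICAL_SET)
            raise ValueError(
                f"{self.name}: not a partition of the canonical alphabet "
                f"(missing {missing}, extra {extra})"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index_of(self, residue: str) -> int:
        """0-based group index of a canonical residue."""
        return self._lookup[residue]

    @property
    def _lookup(self) -> dict[str, int]:
        try:
            return object.__getattribute__(self, "_lookup_cache")
        except AttributeError:
            table = {r: i for i, g in enumerate(self.groups) for r in g}
            object.__setattr__(self, "_lookup_cache", table)
            return table


def _scheme(name: str, named: list[tuple[str, str]]) -> GroupScheme:
    return GroupScheme(
        name=name,
        group_names=tuple(n for n, _ in named),
        groups=tuple(frozenset(members) for _, members in named),
    )


# Five physicochemical classes for the grouped dipeptide composition.
# G is assigned to the aliphatic group only; the negative group is {D, E}
# (the 21st membership some listings carry would break the partition).
GDPC_SCHEME: GroupScheme = _scheme(
    "GDPC5",
    [
        ("aromatic", "WYF"),
        ("positive", "HKR"),
        ("aliphatic", "AIMGLV"),
        ("uncharged", "CTPSQN"),
        ("negative", "DE"),
    ],
)


def _clusters(name: str, spec: str) -> GroupScheme:
    parts = spec.split(";")
    return _scheme(name, [(str(i + 1), members) for i, members in enumerate(parts)])


# Etchebest reduced alphabets; clusters separated by semicolons, verbatim.
RAAA_SCHEMES: dict[int, GroupScheme] = {
    5: _clusters("C5", "G;IVFYW;ALMEQRK;P;NDHSTC"),
    8: _clusters("C8", "G;IV;FYW;ALM;EQRK;P;ND;HSTC"),
    9: _clusters("C9", "G;IV;FYW;ALM;EQRK;P;ND;HS;TC"),
    11: _clusters("C11", "G;IV;FYW;A;LM;EQRK;P;ND;HS;T;C"),
    13: _clusters("C13", "G;IV;FYW;A;L;M;E;QRK;P;ND;HS;T;C"),
}

ALL_SCHEMES: tuple[GroupScheme, ...] = (GDPC_SCHEME, *RAAA_SCHEMES.values())


# Amino acid property values used by type-1 pseudo amino acid composition:
# Tanford-type hydrophobicity, Hopp-Woods hydrophilicity, side-chain mass
# (daltons). Ordered as CANONICAL_RESIDUES.
_RAW_PROPERTIES: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "side_chain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
        "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
        "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
        "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
    },
}

PROPERTY_NAMES: tuple[str, ...] = tuple(_RAW_PROPERTIES)


def standardized_properties() -> np.ndarray:
    """3 x 20 property table, each row standardized to mean 0 and
    population (divide-by-20) standard deviation 1 over the residues,
    columns ordered as :data:`CANONICAL_RESIDUES`."""
    rows = []
    for prop in PROPERTY_NAMES:
        vals = np.array([_RAW_PROPERTIES[prop][r] for r in CANONICAL_RESIDUES])
        rows.append((vals - vals.mean()) / vals.std())  # population std
    return np.vstack(rows)
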