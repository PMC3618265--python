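"""Protein sequence descriptors: amino-acid composition (AAC) and CTD.

A protein is featurized into 167 numbers: 147 CTD descriptors (seven
physicochemical property alphabets x 21 descriptors each) followed by 20
amino-acid composition percentages.

For each property the 20 standard amino acids are partitioned into three
groups and the sequence is rewritten over the alphabet {'1','2','3'}.
From that encoding three descriptor families are computed, all expressed
as percentages:

* Composition (C, 3 values): the percentage of residues in each group.
* Transition (T, 3 values, ordered T12, T13, T23): the percentage of
  adjacent residue pairs whose groups differ, per unordered group pair,
  out of the N-1 adjacent positions.
* Distribution (D, 15 values): for each group, the sequence position
  (as a percentage of the chain length) of the first, 25%, 50%, 75% and
  100% occurrence of that group.

The three-group divisions are the classic ones introduced for protein
fold-class prediction (Dubchak et al.) and used throughout the CTD
literature; the hydrophobicity division reproduces the canonical worked
encoding of MTEITAAMVKELRESTGAGA -> 32132223311311222222.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Three-group divisions of the 20 amino acids for the seven properties,
# in the fixed property order used throughout the package.
_GROUP_TABLES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "normalized_vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

PROPERTIES: tuple[str, ...] = tuple(_GROUP_TABLES)

N_CTD_PER_PROPERTY = 21
N_CTD = N_CTD_PER_PROPERTY * len(PROPERTIES)  # 147
N_AAC = 20
N_PROTEIN_FEATURES = N_CTD + N_AAC  # 167

_QUANTILE_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.00)
_QUANTILE_NAMES = ("first", "25", "50", "75", "100")


class NonStandardResidueError(ValueError):
    """A residue outside the 20 standard one-letter codes was found."""


@dataclass(frozen=True)
class PropertyAlphabet:
    """Total mapping from each standard amino acid to a group in {1,2,3}."""

    property_id: str
    groups: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.groups) != set(STANDARD_AMINO_ACIDS):
            missing = set(STANDARD_AMINO_ACIDS) - set(self.groups)
            raise ValueError(f"alphabet {self.property_id!r} does not cover: {sorted(missing)}")
        if set(self.groups.values()) != {1, 2, 3}:
            raise ValueError(f"alphabet {self.property_id!r} must use exactly groups 1, 2, 3")


def _build_alphabets() -> dict[str, PropertyAlphabet]:
    out = {}
    for prop, table in _GROUP_TABLES.items():
        mapping: dict[str, int] = {}
        for g, members in enumerate(table, start=1):
            for aa in members:
                mapping[aa] = g
        out[prop] = PropertyAlphabet(prop, mapping)
    return out


ALPHABETS: dict[str, PropertyAlphabet] = _build_alphabets()


@dataclass(frozen=True)
class GroupEncoding:
    """A sequence rewritten over {'1','2','3'} with per-group counts."""

    symbols: str
    n1: int
    n2: int
    n3: int

    @property
    def length(self) -> int:
        return len(self.symbols)

    def count(self, group: int) -> int:
        return (self.n1, self.n2, self.n3)[group - 1]


@dataclass(frozen=True)
class ProteinFeatureVector:
    """167 ordered descriptor values with named slices into the blocks.

    ``index_map`` maps each of the seven property names to the slice of
    its 21 CTD values, and ``"aac"`` to the trailing 20-value block; the
    slices are disjoint and cover all 167 positions.
    """

    values: np.ndarray
    index_map: dict[str, slice] = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def block(self, name: str) -> np.ndarray:
        return self.values[self.index_map[name]]


def clean_sequence(residues: str, on_nonstandard: str = "reject") -> str:
    """Validate a residue string, optionally stripping non-standard codes.

    ``on_nonstandard`` is ``"reject"`` (raise, naming the first offending
    character and its 0-based position) or ``"strip"`` (drop X/B/Z/U,
    gaps and anything else outside the 20 standard codes).
    """
    residues = residues.upper()
    if on_nonstandard == "strip":
        return "".join(c for c in residues if c in STANDARD_AMINO_ACIDS)
    for i, c in enumerate(residues):
        if c not in STANDARD_AMINO_ACIDS:
            raise NonStandardResidueError(
                f"non-standard residue {c!r} at position {i}"
            )
    return residues


def encode_property(residues: str, alphabet: str | PropertyAlphabet) -> GroupEncoding:
    """Rewrite ``residues`` over {'1','2','3'} under one property alphabet."""
    if isinstance(alphabet, str):
        alphabet = ALPHABETS[alphabet]
    symbols = []
    counts = [0, 0, 0]
    for i, aa in enumerate(residues):
        g = alphabet.groups.get(aa)
        if g is None:
            raise NonStandardResidueError(
                f"residue {aa!r} at position {i} is not mapped by "
                f"the {alphabet.property_id!r} alphabet"
            )
        symbols.append(str(g))
        counts[g - 1] += 1
    return GroupEncoding("".join(symbols), *counts)


def composition(enc: GroupEncoding) -> tuple[float, float, float]:
    """Percentage of residues in each of the three groups."""
    n = enc.length
    if n == 0:
        raise ValueError("composition undefined for an empty encoding")
    return tuple(enc.count(g) * 100.0 / n for g in (1, 2, 3))


def transition(enc: GroupEncoding) -> tuple[float, float, float]:
    """Percent frequency of adjacent group switches (T12, T13, T23)."""
    n = enc.length
    if n < 2:
        raise ValueError("transition requires at least 2 residues")
    pairs = {"12": 0, "13": 0, "23": 0}
    s = enc.symbols
    for a, b in zip(s, s[1:]):
        if a != b:
            key = a + b if a < b else b + a
            pairs[key] += 1
    return tuple(pairs[k] * 100.0 / (n - 1) for k in ("12", "13", "23"))


def distribution(enc: GroupEncoding) -> tuple[float, ...]:
    """Chain-length percentages locating each group along the sequence.

    For each group g with n_g occurrences, the five values are the
    sequence positions (1-based, scaled by 100/N) of the k-th occurrence
    of g, where k = 1 for "first" and k = max(1, floor(f * n_g)) for
    f in {25%, 50%, 75%, 100%}.  A group absent from the sequence
    contributes five zeros, keeping the vector length fixed.
    """
    n = enc.length
    if n == 0:
        raise ValueError("distribution undefined for an empty encoding")
    out: list[float] = []
    for g in "123":
        positions = [i + 1 for i, c in enumerate(enc.symbols) if c == g]
        if not positions:
            out.extend([0.0] * 5)
            continue
        ng = len(positions)
        for f in _QUANTILE_FRACTIONS:
            k = max(1, math.floor(f * ng))
            out.append(positions[k - 1] * 100.0 / n)
    return tuple(out)


def ctd_block(residues: str, alphabet: str | PropertyAlphabet) -> np.ndarray:
    """The 21 C+T+D descriptors of one property alphabet."""
    enc = encode_property(residues, alphabet)
    return np.array([*composition(enc), *transition(enc), *distribution(enc)])


def ctd_vector(residues: str) -> np.ndarray:
    """All 147 CTD descriptors, properties in the fixed package order."""
    if len(residues) < 2:
        raise ValueError("CTD requires a sequence of at least 2 residues")
    return np.concatenate([ctd_block(residues, p) for p in PROPERTIES])


def aac_vector(residues: str) -> np.ndarray:
    """Amino-acid composition: 20 percentages in alphabetical AA order.

    Reported on the percent scale so that AAC and CTD descriptors are
    commensurate; the 20 values sum to 100.
    """
    if not residues:
        raise ValueError("AAC undefined for an empty sequence")
    n = len(residues)
    counts = {aa: 0 for aa in STANDARD_AMINO_ACIDS}
    for i, aa in enumerate(residues):
        if aa not in counts:
            raise NonStandardResidueError(f"non-standard residue {aa!r} at position {i}")
        counts[aa] += 1
    return np.array([counts[aa] * 100.0 / n for aa in STANDARD_AMINO_ACIDS])


def _index_map() -> dict[str, slice]:
    m: dict[str, slice] = {}
    off = 0
    for p in PROPERTIES:
        m[p] = slice(off, off + N_CTD_PER_PROPERTY)
        off += N_CTD_PER_PROPERTY
    m["aac"] = slice(off, off + N_AAC)
    return m


INDEX_MAP: dict[str, slice] = _index_map()


def protein_features(residues: str) -> ProteinFeatureVector:
    """The full 167-value descriptor vector: 147 CTD then 20 AAC."""
    values = np.concatenate([ctd_vector(residues), aac_vector(residues)])
    assert len(values) == N_PROTEIN_FEATURES
    return ProteinFeatureVector(values, dict(INDEX_MAP))


def protein_feature_names() -> list[str]:
    """Column names for the 167 descriptors, e.g. ``hydrophobicity.T.1-3``."""
    names: list[str] = []
    for p in PROPERTIES:
        names.extend(f"{p}.C.{g}" for g in "123")
        names.extend(f"{p}.T.{pair}" for pair in ("1-2", "1-3", "2-3"))
        for g in "123":
            names.extend(f"{p}.D.{g}.{q}" for q in _QUANTILE_NAMES)
    names.extend(f"aac.{aa}" for aa in STANDARD_AMINO_ACIDS)
    return names
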