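"""Sequence descriptors for intrinsically disordered regions (IDRs).

Seven fixed-dimension feature families describe one IDR each:

====================  ====  ============================================
family                 dim  description
====================  ====  ============================================
chemical_composition     5  fractions of charge/polarity residue classes
aa_composition          20  per-residue fractions
composition_dubchak    125  aa_composition + 5x CTD property blocks
occurrence_dubchak     125  aa_occurrence + 5x CTD property blocks
sequence_bigrams       400  adjacent ordered-pair frequencies
alternate_bigrams      400  one-gap ordered-pair frequencies
profile_bigrams        400  PSSM-weighted transition frequencies
====================  ====  ============================================

All vectors use the canonical alphabet order ``ACDEFGHIKLMNPQRSTVWY``;
bigram vectors are flattened row-major (first residue varies slowest) so
sequence- and profile-based bigrams share a column order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger("idrfunc")

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: residues outside the 20-letter alphabet are dropped during sanitization
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ")

# Chemical residue classes (fixed output order). Histidine joins the
# positively-chargeable class so the five classes partition the alphabet
# and the fractions sum to 1.
CHEMICAL_CLASSES: tuple[tuple[str, frozenset[str]], ...] = (
    ("positive", frozenset("RKH")),
    ("negative", frozenset("DE")),
    ("polar", frozenset("STNQYC")),
    ("hydrophobic", frozenset("AVLIMFW")),
    ("special", frozenset("PG")),
)

BIGRAM_NAMES = tuple(a + b for a in ALPHABET for b in ALPHABET)

FAMILY_DIMENSIONS: Mapping[str, int] = {
    "chemical_composition": 5,
    "aa_composition": 20,
    "composition_dubchak": 125,
    "occurrence_dubchak": 125,
    "sequence_bigrams": 400,
    "alternate_bigrams": 400,
    "profile_bigrams": 400,
}

#: families computed from the raw sequence (all but profile_bigrams)
SEQUENCE_FAMILIES = tuple(f for f in FAMILY_DIMENSIONS if f != "profile_bigrams")
ALL_FAMILIES = tuple(FAMILY_DIMENSIONS)


class FeatureError(ValueError):
    """Invalid input to a feature extractor."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def sanitize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and drop residues outside the 20-letter alphabet.

    Returns the clean sequence and the number of dropped residues.
    """
    up = raw.upper()
    clean = "".join(c for c in up if c in AA_INDEX)
    return clean, len(up) - len(clean)


@dataclass(frozen=True)
class IDRSequence:
    """One intrinsically disordered region with its parent protein id."""

    idr_id: str
    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FeatureError(f"IDR {self.idr_id!r}: empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise FeatureError(
                f"IDR {self.idr_id!r}: non-standard residues {sorted(bad)}; "
                "sanitize before construction"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PSSMatrix:
    """Row-normalized L x 20 per-position amino-acid probabilities."""

    idr_id: str
    probs: np.ndarray
    column_order: str = ALPHABET

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 20:
            raise FeatureError(f"PSSM {self.idr_id!r}: expected L x 20, got {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise FeatureError(f"PSSM {self.idr_id!r}: entries outside [0, 1]")
        if self.column_order != ALPHABET:
            raise FeatureError("PSSM columns must be in canonical alphabet order")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def is_row_normalized(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.probs.sum(axis=1) - 1.0) <= tol))


@dataclass(frozen=True)
class FeatureVector:
    """A named fixed-dimension numeric descriptor of one IDR."""

    idr_id: str
    family: str
    values: np.ndarray
    component_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.family not in FAMILY_DIMENSIONS:
            raise FeatureError(f"unknown feature family {self.family!r}")
        d = FAMILY_DIMENSIONS[self.family]
        if v.shape != (d,) or len(self.component_names) != d:
            raise FeatureError(
                f"{self.family}: expected dimension {d}, got values {v.shape} "
                f"with {len(self.component_names)} names"
            )

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PropertyPartition:
    """A 3-group split of the 20 amino acids for one physicochemical property."""

    property_name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) != 3:
            raise FeatureError(f"{self.property_name}: need exactly 3 groups")
        union = frozenset().union(*groups)
        if union != frozenset(ALPHABET) or sum(map(len, groups)) != 20:
            raise FeatureError(
                f"{self.property_name}: groups must partition the 20-letter alphabet"
            )

    def group_of(self, residue: str) -> int:
        for g, members in enumerate(self.groups):
            if residue in members:
                return g
        raise FeatureError(f"residue {residue!r} not in partition")


def _partition(name: str, g1: str, g2: str, g3: str) -> PropertyPartition:
    return PropertyPartition(name, (frozenset(g1), frozenset(g2), frozenset(g3)))


# Standard 3-group splits used in fold-recognition descriptor sets
# (hydrophobicity, normalized van der Waals volume, polarity, polarizability)
# plus helix/strand/coil former classes for the secondary-structure property.
# These are configuration: pass a different mapping to dubchak_features to
# override.
DEFAULT_PARTITIONS: Mapping[str, PropertyPartition] = {
    "hydrophobicity": _partition("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": _partition("vdw_volume", "GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": _partition("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": _partition("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    "secondary_structure": _partition("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
}

#: fixed concatenation order of the CTD property blocks
DUBCHAK_PROPERTY_ORDER = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "secondary_structure",
)


# ---------------------------------------------------------------------------
# composition families
# ---------------------------------------------------------------------------


def chemical_composition(seq: IDRSequence) -> FeatureVector:
    """Fractions of the 5 chemical residue classes.

    Order: positive (R,K), negative (D,E), polar (S,T,N,Q,Y,C),
    hydrophobic (A,V,L,I,M,F,W), special (P,G). Sums to 1.
    """
    counts = np.zeros(5)
    for i, (_, members) in enumerate(CHEMICAL_CLASSES):
        counts[i] = sum(seq.residues.count(r) for r in members)
    values = counts / seq.length
    names = tuple(name for name, _ in CHEMICAL_CLASSES)
    return FeatureVector(seq.idr_id, "chemical_composition", values, names)


def _aa_counts(seq: IDRSequence) -> np.ndarray:
    counts = np.zeros(20)
    for r in seq.residues:
        counts[AA_INDEX[r]] += 1
    return counts


def aa_composition(seq: IDRSequence) -> FeatureVector:
    """Fraction of each of the 20 amino acids; sums to 1."""
    values = _aa_counts(seq) / seq.length
    return FeatureVector(seq.idr_id, "aa_composition", values, tuple(ALPHABET))


def aa_occurrence(seq: IDRSequence) -> FeatureVector:
    """Un-normalized residue counts; sums to the sequence length.

    Exposed as a 20-vector in the same order as :func:`aa_composition`;
    not a registered family on its own — it forms the first 20 components
    of ``occurrence_dubchak``.
    """
    values = _aa_counts(seq)
    return FeatureVector(seq.idr_id, "aa_composition", values, tuple(ALPHABET))


# ---------------------------------------------------------------------------
# CTD (composition / transition / distribution) blocks
# ---------------------------------------------------------------------------


def ctd_block(seq: IDRSequence, partition: PropertyPartition) -> np.ndarray:
    """21 CTD values for one property partition.

    Layout: ``[C1, C2, C3, T12, T13, T23, D...]`` where D holds, per group,
    the 1-based positions of the first, 25%, 50%, 75% and last occurrence
    divided by L (0 for absent groups).
    """
    L = seq.length
    groups = [partition.group_of(r) for r in seq.residues]

    comp = np.bincount(groups, minlength=3) / L

    trans = np.zeros(3)  # T12, T13, T23
    if L > 1:
        pair_slot = {(0, 1): 0, (1, 0): 0, (0, 2): 1, (2, 0): 1, (1, 2): 2, (2, 1): 2}
        for a, b in zip(groups, groups[1:]):
            slot = pair_slot.get((a, b))
            if slot is not None:
                trans[slot] += 1
        trans /= L - 1

    dist = np.zeros(15)
    for g in range(3):
        positions = [i + 1 for i, grp in enumerate(groups) if grp == g]
        n_g = len(positions)
        if n_g == 0:
            continue
        anchors = (1, math.ceil(0.25 * n_g), math.ceil(0.50 * n_g), math.ceil(0.75 * n_g), n_g)
        for k, a in enumerate(anchors):
            dist[g * 5 + k] = positions[max(a, 1) - 1] / L

    return np.concatenate([comp, trans, dist])


def _ctd_names(property_name: str) -> tuple[str, ...]:
    names = [f"{property_name}:C{g}" for g in (1, 2, 3)]
    names += [f"{property_name}:T{p}" for p in ("12", "13", "23")]
    for g in (1, 2, 3):
        names += [f"{property_name}:D{g}_{a}" for a in ("first", "25", "50", "75", "100")]
    return tuple(names)


def dubchak_features(
    seq: IDRSequence,
    mode: Literal["composition", "occurrence"],
    partitions: Mapping[str, PropertyPartition] = DEFAULT_PARTITIONS,
) -> FeatureVector:
    """125-dim descriptor: 20 residue stats + 5 properties x 21 CTD values.

    ``mode='composition'`` prefixes residue fractions, ``mode='occurrence'``
    raw counts; the CTD blocks are identical in both modes.
    """
    if mode == "composition":
        head = _aa_counts(seq) / seq.length
        family = "composition_dubchak"
        head_names = tuple(f"comp:{a}" for a in ALPHABET)
    elif mode == "occurrence":
        head = _aa_counts(seq)
        family = "occurrence_dubchak"
        head_names = tuple(f"occ:{a}" for a in ALPHABET)
    else:
        raise FeatureError(f"unknown mode {mode!r}")

    missing = [p for p in DUBCHAK_PROPERTY_ORDER if p not in partitions]
    if missing:
        raise FeatureError(f"missing property partitions: {missing}")

    blocks = [head]
    names: list[str] = list(head_names)
    for prop in DUBCHAK_PROPERTY_ORDER:
        blocks.append(ctd_block(seq, partitions[prop]))
        names.extend(_ctd_names(prop))
    return FeatureVector(seq.idr_id, family, np.concatenate(blocks), tuple(names))


# ---------------------------------------------------------------------------
# bigram families
# ---------------------------------------------------------------------------


def _pair_counts(seq: IDRSequence, gap: int) -> np.ndarray:
    counts = np.zeros((20, 20))
    for a, b in zip(seq.residues, seq.residues[1 + gap:]):
        counts[AA_INDEX[a], AA_INDEX[b]] += 1
    return counts


def sequence_bigrams(seq: IDRSequence) -> FeatureVector:
    """Frequencies of the 400 ordered adjacent residue pairs.

    Counts are divided by the number of windows (L-1) so the vector sums
    to 1. Sequences with L < 2 yield an all-zero vector with a warning.
    """
    if seq.length < 2:
        logger.warning("sequence_bigrams: IDR %s has L=%d < 2; zero vector", seq.idr_id, seq.length)
        values = np.zeros(400)
    else:
        values = _pair_counts(seq, gap=0).ravel() / (seq.length - 1)
    return FeatureVector(seq.idr_id, "sequence_bigrams", values, BIGRAM_NAMES)


def alternate_bigrams(seq: IDRSequence) -> FeatureVector:
    """Frequencies of the 400 ordered residue pairs separated by one residue.

    Counts divided by (L-2); sums to 1. L < 3 yields zeros with a warning.
    """
    if seq.length < 3:
        logger.warning("alternate_bigrams: IDR %s has L=%d < 3; zero vector", seq.idr_id, seq.length)
        values = np.zeros(400)
    else:
        values = _pair_counts(seq, gap=1).ravel() / (seq.length - 2)
    return FeatureVector(seq.idr_id, "alternate_bigrams", values, BIGRAM_NAMES)


def profile_bigrams(pssm: PSSMatrix) -> FeatureVector:
    """PSSM transition frequencies T[m, n] = sum_i e[i, m] * e[i+1, n].

    The 20 x 20 transition matrix is flattened row-major, matching
    :func:`sequence_bigrams` column order; the flattened vector sums to
    L - 1 for row-normalized profiles. For a one-hot profile encoding a
    sequence s the result equals (L - 1) * sequence_bigrams(s).
    """
    if not pssm.is_row_normalized():
        raise FeatureError(f"PSSM {pssm.idr_id!r}: rows are not normalized to 1")
    if pssm.length < 2:
        logger.warning("profile_bigrams: IDR %s has L=%d < 2; zero vector", pssm.idr_id, pssm.length)
        values = np.zeros(400)
    else:
        trans = pssm.probs[:-1].T @ pssm.probs[1:]
        values = trans.ravel()
    names = tuple(f"pssm:{b}" for b in BIGRAM_NAMES)
    return FeatureVector(pssm.idr_id, "profile_bigrams", values, names)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def extract(
    family: str,
    seq: IDRSequence | None = None,
    pssm: PSSMatrix | None = None,
    partitions: Mapping[str, PropertyPartition] = DEFAULT_PARTITIONS,
) -> FeatureVector:
    """Compute one feature family for one IDR.

    ``profile_bigrams`` requires ``pssm``; every other family requires ``seq``.
    """
    if family == "profile_bigrams":
        if pssm is None:
            raise FeatureError("profile_bigrams requires a PSSM")
        return profile_bigrams(pssm)
    if seq is None:
        raise FeatureError(f"{family} requires a sequence")
    if family == "chemical_composition":
        return chemical_composition(seq)
    if family == "aa_composition":
        return aa_composition(seq)
    if family == "composition_dubchak":
        return dubchak_features(seq, "composition", partitions)
    if family == "occurrence_dubchak":
        return dubchak_features(seq, "occurrence", partitions)
    if family == "sequence_bigrams":
        return sequence_bigrams(seq)
    if family == "alternate_bigrams":
        return alternate_bigrams(seq)
    raise FeatureError(f"unknown feature family {family!r}")


def feature_matrix(
    family: str,
    sequences: Sequence[IDRSequence],
    pssms: Mapping[str, PSSMatrix] | None = None,
    partitions: Mapping[str, PropertyPartition] = DEFAULT_PARTITIONS,
) -> tuple[list[str], np.ndarray, tuple[str, ...]]:
    """Stack one family over many IDRs.

    Returns ``(idr_ids, X, component_names)``. For ``profile_bigrams``,
    IDRs without a PSSM are omitted (and counted in the log), mirroring
    profile pipelines where the homology search fails for some regions.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    names: tuple[str, ...] | None = None
    n_missing = 0
    for seq in sequences:
        if family == "profile_bigrams":
            p = (pssms or {}).get(seq.idr_id)
            if p is None:
                n_missing += 1
                continue
            fv = profile_bigrams(p)
        else:
            fv = extract(family, seq=seq, partitions=partitions)
        rows.append(fv.values)
        ids.append(seq.idr_id)
        names = fv.component_names
    if n_missing:
        logger.warning("feature_matrix[%s]: %d IDRs without PSSM omitted", family, n_missing)
    if not rows:
        raise FeatureError(f"feature_matrix[{family}]: no usable IDRs")
    assert names is not None
    return ids, np.vstack(rows), names
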