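"""Seeded synthetic datasets with the structure the analysis assumes.

Emulates a multi-label IDR function dataset: proteins carrying one or more
disordered regions, a two-level GO Slim hierarchy (leaf terms with immediate
parents), term-linked residue-composition signals, and noisy position
profiles (PSSMs) per IDR. Every IDR inherits its protein's full term set.

The defaults mirror the shape of large human IDR collections: ~1.7 IDRs per
protein (uniform 1-3), IDR lengths 30-300, a disorder-like background
composition (elevated P/S/E/K, depleted W/C/F/I) with D+E at 12%, and one
"acidic" signal term that raises D+E to 30% in its positive proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .features import ALPHABET, AA_INDEX, IDRSequence, PSSMatrix

# Disorder-like background residue frequencies (sum to 1; D+E = 0.12).
BACKGROUND_FREQS: Mapping[str, float] = {
    "A": 0.065, "C": 0.010, "D": 0.050, "E": 0.070, "F": 0.020,
    "G": 0.085, "H": 0.020, "I": 0.025, "K": 0.070, "L": 0.055,
    "M": 0.015, "N": 0.055, "P": 0.090, "Q": 0.060, "R": 0.055,
    "S": 0.105, "T": 0.080, "V": 0.045, "W": 0.005, "Y": 0.020,
}

_BG = np.array([BACKGROUND_FREQS[a] for a in ALPHABET])
assert abs(_BG.sum() - 1.0) < 1e-9

#: term id of the default acidic signal leaf
DEFAULT_SIGNAL_TERM = "GO:0000101"


def default_signal_map() -> dict[str, tuple[frozenset[str], float]]:
    """One leaf term whose positive proteins have D+E enriched to 30%."""
    return {DEFAULT_SIGNAL_TERM: (frozenset("DE"), 0.30)}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``signal_map`` maps a leaf term to (residue set, total enriched
    fraction): IDRs of proteins annotated with that term draw the listed
    residues with the given total frequency (split proportionally to the
    background within the set), everything else rescaled.
    """

    n_proteins: int = 250
    idrs_per_protein: tuple[int, int] = (1, 3)  # inclusive uniform range
    idr_length: tuple[int, int] = (30, 300)  # inclusive uniform range
    n_leaf_terms: int = 8
    n_parent_terms: int = 4
    terms_per_protein: tuple[int, int] = (1, 6)  # inclusive, capped at n_leaf_terms
    signal_map: Mapping[str, tuple[frozenset[str], float]] = field(default_factory=default_signal_map)
    background: Mapping[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    pssm_concentration: float = 30.0
    pssm_background_weight: float = 0.5
    missing_pssm_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.array([self.background[a] for a in ALPHABET])
        if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg < 0):
            raise ValueError("background frequencies must be non-negative and sum to 1")
        total = 0.0
        seen: set[str] = set()
        for term, (residues, frac) in self.signal_map.items():
            if not 0.0 < frac < 1.0:
                raise ValueError(f"signal fraction for {term} must be in (0, 1)")
            if seen & set(residues):
                raise ValueError("signal residue sets must be disjoint across terms")
            seen |= set(residues)
            total += frac
        if total >= 1.0:
            raise ValueError(f"signal fractions sum to {total} >= 1")
        if self.pssm_concentration <= 0:
            raise ValueError("pssm_concentration must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """Sequences, PSSMs, raw (unexpanded) annotations and the term hierarchy."""

    sequences: list[IDRSequence]
    pssms: dict[str, PSSMatrix]
    annotations: dict[str, frozenset[str]]  # idr_id -> raw leaf terms
    protein_of: dict[str, str]  # idr_id -> protein_id
    parent_map: dict[str, str]  # leaf term -> parent term
    truth: Mapping[str, tuple[frozenset[str], float]]  # signal map used


def term_hierarchy(n_leaf_terms: int = 8, n_parent_terms: int = 4) -> tuple[list[str], dict[str, str]]:
    """Leaf term ids GO:00001xx and a round-robin leaf -> parent map."""
    if n_parent_terms > n_leaf_terms:
        raise ValueError("cannot have more parents than leaves")
    leaves = [f"GO:{100 + i:07d}" for i in range(1, n_leaf_terms + 1)]
    parents = [f"GO:{200 + i:07d}" for i in range(1, n_parent_terms + 1)]
    parent_map = {leaf: parents[i % n_parent_terms] for i, leaf in enumerate(leaves)}
    return leaves, parent_map


def _composition_for_terms(
    terms: frozenset[str],
    signal_map: Mapping[str, tuple[frozenset[str], float]],
    bg: np.ndarray,
) -> np.ndarray:
    """Background composition reshaped by the union of the terms' signals."""
    probs = bg.copy()
    enriched_idx: list[int] = []
    for term in terms:
        if term not in signal_map:
            continue
        residues, frac = signal_map[term]
        idx = [AA_INDEX[r] for r in residues]
        within = bg[idx] / bg[idx].sum()
        probs[idx] = frac * within
        enriched_idx.extend(idx)
    if enriched_idx:
        rest = np.setdiff1d(np.arange(20), np.array(enriched_idx))
        remaining = 1.0 - probs[np.array(enriched_idx)].sum()
        probs[rest] = bg[rest] / bg[rest].sum() * remaining
    return probs


def generate_pssm(
    seq: IDRSequence,
    concentration: float = 30.0,
    rng: np.random.Generator | int | None = None,
    background_weight: float = 0.5,
    background: np.ndarray | None = None,
) -> PSSMatrix:
    """Noisy row-normalized profile centred on the sequence.

    Row i is Dirichlet-distributed with concentration vector
    ``concentration * one_hot(residue_i) + background_weight * 20 * bg``,
    a one-hot centre mixed with a substitution-like background. As the
    concentration grows the rows sharpen toward one-hot, so the profile
    bigrams converge to (L-1) times the sequence bigrams.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(rng)
    bg = _BG if background is None else background
    alpha = background_weight * 20.0 * np.tile(bg, (seq.length, 1))
    idx = np.array([AA_INDEX[r] for r in seq.residues])
    alpha[np.arange(seq.length), idx] += concentration
    # Dirichlet via normalized gammas (vectorized over rows)
    g = rng.gamma(shape=alpha)
    g = np.maximum(g, 1e-300)
    probs = g / g.sum(axis=1, keepdims=True)
    return PSSMatrix(idr_id=seq.idr_id, probs=probs)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full dataset: proteins -> terms -> IDR sequences -> PSSMs.

    Deterministic for a fixed ``config.seed``. Every IDR of a protein
    carries the protein's full (raw, unexpanded) leaf-term set; ancestor
    expansion is a downstream, explicit step.
    """
    rng = np.random.default_rng(config.seed)
    leaves, parent_map = term_hierarchy(config.n_leaf_terms, config.n_parent_terms)
    bg = np.array([config.background[a] for a in ALPHABET])
    aa = np.array(list(ALPHABET))

    sequences: list[IDRSequence] = []
    pssms: dict[str, PSSMatrix] = {}
    annotations: dict[str, frozenset[str]] = {}
    protein_of: dict[str, str] = {}

    lo_t, hi_t = config.terms_per_protein
    hi_t = min(hi_t, config.n_leaf_terms)
    for p in range(1, config.n_proteins + 1):
        protein_id = f"PROT{p:05d}"
        n_terms = int(rng.integers(lo_t, hi_t + 1))
        terms = frozenset(rng.choice(leaves, size=n_terms, replace=False))
        probs = _composition_for_terms(terms, config.signal_map, bg)
        n_idrs = int(rng.integers(config.idrs_per_protein[0], config.idrs_per_protein[1] + 1))
        for j in range(1, n_idrs + 1):
            idr_id = f"{protein_id}_IDR{j}"
            L = int(rng.integers(config.idr_length[0], config.idr_length[1] + 1))
            residues = "".join(rng.choice(aa, size=L, p=probs))
            seq = IDRSequence(idr_id=idr_id, protein_id=protein_id, residues=residues)
            sequences.append(seq)
            annotations[idr_id] = terms
            protein_of[idr_id] = protein_id
            if rng.random() >= config.missing_pssm_fraction:
                pssms[idr_id] = generate_pssm(
                    seq,
                    concentration=config.pssm_concentration,
                    rng=rng,
                    background_weight=config.pssm_background_weight,
                    background=bg,
                )
    return SyntheticDataset(
        sequences=sequences,
        pssms=pssms,
        annotations=annotations,
        protein_of=protein_of,
        parent_map=parent_map,
        truth=dict(config.signal_map),
    )


def permute_labels(ds: SyntheticDataset, seed: int = 0) -> SyntheticDataset:
    """Null dataset: protein term sets shuffled across proteins.

    Permuting at the protein level (IDRs keep their protein's permuted
    set) breaks any sequence-label association while preserving the label
    marginals and the IDRs-share-protein-labels structure.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted({ds.protein_of[r] for r in ds.annotations})
    term_sets = {p: next(ds.annotations[r] for r in ds.annotations if ds.protein_of[r] == p) for p in proteins}
    perm = rng.permutation(len(proteins))
    shuffled = {proteins[i]: term_sets[proteins[int(j)]] for i, j in enumerate(perm)}
    new_annotations = {r: shuffled[ds.protein_of[r]] for r in ds.annotations}
    return SyntheticDataset(
        sequences=ds.sequences,
        pssms=ds.pssms,
        annotations=new_annotations,
        protein_of=ds.protein_of,
        parent_map=ds.parent_map,
        truth={},
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four-file bundle read back by the io module.

    Emits ``idrs.fasta``, ``pssms/<idr_id>.pssm`` (PSI-BLAST ASCII
    dialect), ``annotations.tsv`` and ``parent_map.tsv``; round-trips
    losslessly through the package readers (PSSM rows to 4 decimals).
    """
    from . import io as idrio  # deferred: io imports features, not synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "idrs.fasta"
    idrio.write_fasta(ds.sequences, fasta)

    pssm_dir = out / "pssms"
    pssm_dir.mkdir(exist_ok=True)
    seq_by_id = {s.idr_id: s for s in ds.sequences}
    for idr_id, pssm in ds.pssms.items():
        idrio.write_pssm_ascii(pssm, seq_by_id[idr_id], pssm_dir / f"{idr_id}.pssm")

    ann = out / "annotations.tsv"
    idrio.write_annotations(ds.annotations, ds.protein_of, ann)

    pm = out / "parent_map.tsv"
    idrio.write_parent_map(ds.parent_map, pm)
    return {"fasta": fasta, "pssm_dir": pssm_dir, "annotations": ann, "parent_map": pm}
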