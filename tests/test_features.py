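"""Feature extractors: worked examples, enumeration oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idrfunc import features
from idrfunc.features import (
    ALPHABET,
    AA_INDEX,
    DEFAULT_PARTITIONS,
    FAMILY_DIMENSIONS,
    FeatureError,
    IDRSequence,
    PSSMatrix,
    PropertyPartition,
)

from conftest import random_sequence

seq_strategy = st.text(alphabet=ALPHABET, min_size=3, max_size=200)


def mkseq(residues: str) -> IDRSequence:
    return IDRSequence(idr_id="i", protein_id="p", residues=residues)


def one_hot_pssm(seq: IDRSequence) -> PSSMatrix:
    probs = np.zeros((seq.length, 20))
    for i, r in enumerate(seq.residues):
        probs[i, AA_INDEX[r]] = 1.0
    return PSSMatrix(idr_id=seq.idr_id, probs=probs)


# ---------------------------------------------------------------------------
# dimensions and normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("family,dim", sorted(FAMILY_DIMENSIONS.items()))
def test_family_dimensions(rng, family, dim):
    """Each family emits its fixed dimension for arbitrary valid inputs."""
    for length in (3, 17, 101):
        seq = random_sequence(rng, length)
        fv = features.extract(family, seq=seq, pssm=one_hot_pssm(seq))
        assert fv.dimension == dim == len(fv.component_names)


def test_normalization_invariants(rng):
    """Composition/bigram vectors sum to 1, occurrence to L, profile to L-1."""
    for _ in range(100):
        L = int(rng.integers(3, 201))
        seq = random_sequence(rng, L)
        assert features.chemical_composition(seq).values.sum() == pytest.approx(1, abs=1e-9)
        assert features.aa_composition(seq).values.sum() == pytest.approx(1, abs=1e-9)
        assert features.aa_occurrence(seq).values.sum() == L
        assert features.sequence_bigrams(seq).values.sum() == pytest.approx(1, abs=1e-9)
        assert features.alternate_bigrams(seq).values.sum() == pytest.approx(1, abs=1e-9)
        assert features.profile_bigrams(one_hot_pssm(seq)).values.sum() == pytest.approx(L - 1, abs=1e-6)


# ---------------------------------------------------------------------------
# composition families
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "residues,expected",
    [
        ("RK", [1, 0, 0, 0, 0]),
        ("PG", [0, 0, 0, 0, 1]),
        ("RKDESTAVPG", [0.2, 0.2, 0.2, 0.2, 0.2]),  # 2 residues per class
    ],
)
def test_chemical_composition_examples(residues, expected):
    fv = features.chemical_composition(mkseq(residues))
    np.testing.assert_allclose(fv.values, expected)
    assert fv.component_names == ("positive", "negative", "polar", "hydrophobic", "special")


def test_aa_composition_examples():
    homo = features.aa_composition(mkseq("AAAA"))
    assert homo.values[AA_INDEX["A"]] == 1.0 and homo.values.sum() == 1.0
    each_once = features.aa_composition(mkseq(ALPHABET))
    np.testing.assert_allclose(each_once.values, np.full(20, 0.05))


def test_aa_occurrence_examples():
    fv = features.aa_occurrence(mkseq("AAAA"))
    assert fv.values[AA_INDEX["A"]] == 4 and fv.values.sum() == 4
    fv = features.aa_occurrence(mkseq("AC"))
    assert fv.values[AA_INDEX["A"]] == 1 and fv.values[AA_INDEX["C"]] == 1


def test_empty_sequence_rejected():
    with pytest.raises(FeatureError):
        IDRSequence("i", "p", "")


def test_unsanitized_sequence_rejected():
    with pytest.raises(FeatureError):
        IDRSequence("i", "p", "AXA")


def test_sanitize_drops_ambiguous_residues():
    clean, dropped = features.sanitize_sequence("acXBdeZUO")
    assert clean == "ACDE" and dropped == 5


@given(st.text(alphabet=ALPHABET, min_size=1, max_size=60), st.randoms(use_true_random=False))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_composition_families_permutation_invariant(residues, rnd):
    shuffled = list(residues)
    rnd.shuffle(shuffled)
    a, b = mkseq(residues), mkseq("".join(shuffled))
    np.testing.assert_allclose(features.chemical_composition(a).values, features.chemical_composition(b).values)
    np.testing.assert_allclose(features.aa_composition(a).values, features.aa_composition(b).values)
    np.testing.assert_allclose(features.aa_occurrence(a).values, features.aa_occurrence(b).values)


def test_sequence_bigrams_not_permutation_invariant():
    a = features.sequence_bigrams(mkseq("ACC")).values
    b = features.sequence_bigrams(mkseq("CAC")).values
    assert not np.allclose(a, b)


# ---------------------------------------------------------------------------
# CTD blocks
# ---------------------------------------------------------------------------


def ctd_oracle(residues: str, partition: PropertyPartition) -> np.ndarray:
    """Independent brute-force CTD: enumerate positions and adjacent pairs."""
    L = len(residues)
    g = [partition.group_of(r) for r in residues]
    out = []
    for k in range(3):
        out.append(sum(1 for x in g if x == k) / L)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        n = sum(1 for i in range(L - 1) if {g[i], g[i + 1]} == {a, b})
        out.append(n / (L - 1) if L > 1 else 0.0)
    for k in range(3):
        pos = [i + 1 for i in range(L) if g[i] == k]
        if not pos:
            out.extend([0.0] * 5)
            continue
        n = len(pos)
        for q in (1, math.ceil(0.25 * n), math.ceil(0.5 * n), math.ceil(0.75 * n), n):
            out.append(pos[max(q, 1) - 1] / L)
    return np.array(out)


def test_ctd_homopolymer_in_group1():
    part = DEFAULT_PARTITIONS["hydrophobicity"]
    residue = sorted(part.groups[0])[0]
    L = 6
    block = features.ctd_block(mkseq(residue * L), part)
    np.testing.assert_allclose(block[:3], [1, 0, 0])
    np.testing.assert_allclose(block[3:6], 0)
    np.testing.assert_allclose(block[6:11], [1 / L, 2 / L, 3 / L, 5 / L, 1.0])
    np.testing.assert_allclose(block[11:], 0)


def test_ctd_single_boundary_transition():
    # A and D fall in different hydrophobicity groups (neutral vs polar)
    part = DEFAULT_PARTITIONS["hydrophobicity"]
    ga, gd = part.group_of("A"), part.group_of("D")
    assert ga != gd
    block = features.ctd_block(mkseq("AD"), part)
    slot = {frozenset((0, 1)): 0, frozenset((0, 2)): 1, frozenset((1, 2)): 2}[frozenset((ga, gd))]
    expected = np.zeros(3)
    expected[slot] = 1.0
    np.testing.assert_allclose(block[3:6], expected)


@pytest.mark.parametrize("prop", sorted(DEFAULT_PARTITIONS))
def test_ctd_matches_enumeration_oracle(rng, prop):
    part = DEFAULT_PARTITIONS[prop]
    for _ in range(20):
        seq = random_sequence(rng, 30)
        np.testing.assert_allclose(features.ctd_block(seq, part), ctd_oracle(seq.residues, part), atol=1e-12)


def test_partition_must_cover_alphabet():
    with pytest.raises(FeatureError):
        PropertyPartition("bad", (frozenset("A"), frozenset("C"), frozenset("D")))


def test_dubchak_concatenation_order(rng):
    seq = random_sequence(rng, 40)
    comp = features.dubchak_features(seq, "composition")
    occ = features.dubchak_features(seq, "occurrence")
    assert comp.dimension == occ.dimension == 125
    np.testing.assert_allclose(comp.values[:20], features.aa_composition(seq).values)
    np.testing.assert_allclose(occ.values[:20], features.aa_occurrence(seq).values)
    # CTD tail identical between modes
    np.testing.assert_allclose(comp.values[20:], occ.values[20:])


def test_dubchak_missing_partition_rejected(rng):
    with pytest.raises(FeatureError, match="missing"):
        features.dubchak_features(random_sequence(rng, 10), "composition", partitions={})


# ---------------------------------------------------------------------------
# bigram families
# ---------------------------------------------------------------------------


def bigram_oracle(residues: str, gap: int) -> np.ndarray:
    """Exhaustive enumeration over all 400 ordered pairs."""
    L = len(residues)
    windows = L - 1 - gap
    out = np.zeros(400)
    if windows < 1:
        return out
    for m, a in enumerate(ALPHABET):
        for n, b in enumerate(ALPHABET):
            count = sum(
                1 for i in range(windows) if residues[i] == a and residues[i + 1 + gap] == b
            )
            out[m * 20 + n] = count / windows
    return out


def test_sequence_bigram_examples():
    fv = features.sequence_bigrams(mkseq("AA"))
    assert fv.values[0] == 1.0 and fv.values.sum() == 1.0
    fv = features.sequence_bigrams(mkseq("ACA"))
    assert fv.values[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == 0.5
    assert fv.values[AA_INDEX["C"] * 20 + AA_INDEX["A"]] == 0.5


def test_alternate_bigram_examples():
    fv = features.alternate_bigrams(mkseq("ACA"))
    assert fv.values[0] == 1.0
    fv = features.alternate_bigrams(mkseq("ACDE"))
    assert fv.values[AA_INDEX["A"] * 20 + AA_INDEX["D"]] == 0.5
    assert fv.values[AA_INDEX["C"] * 20 + AA_INDEX["E"]] == 0.5


@given(seq_strategy)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_bigrams_match_enumeration_oracle(residues):
    np.testing.assert_allclose(
        features.sequence_bigrams(mkseq(residues)).values, bigram_oracle(residues, gap=0), atol=1e-12
    )
    np.testing.assert_allclose(
        features.alternate_bigrams(mkseq(residues)).values, bigram_oracle(residues, gap=1), atol=1e-12
    )


def test_short_sequences_give_zero_bigram_vectors():
    assert features.sequence_bigrams(mkseq("A")).values.sum() == 0
    assert features.alternate_bigrams(mkseq("AC")).values.sum() == 0


# ---------------------------------------------------------------------------
# profile bigrams
# ---------------------------------------------------------------------------


def test_profile_bigrams_delta_rows():
    probs = np.zeros((2, 20))
    probs[0, AA_INDEX["A"]] = 1.0
    probs[1, AA_INDEX["C"]] = 1.0
    fv = features.profile_bigrams(PSSMatrix("i", probs))
    assert fv.values[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == 1.0
    assert fv.values.sum() == 1.0


@pytest.mark.parametrize("L", [2, 5, 50])
def test_profile_bigrams_uniform_rows_closed_form(L):
    """Uniform rows: every transition component equals (L-1)/400."""
    fv = features.profile_bigrams(PSSMatrix("i", np.full((L, 20), 1 / 20)))
    np.testing.assert_allclose(fv.values, np.full(400, (L - 1) / 400), atol=1e-12)


def test_profile_bigrams_one_hot_equals_scaled_sequence_bigrams(rng):
    for _ in range(20):
        seq = random_sequence(rng, int(rng.integers(3, 120)))
        pb = features.profile_bigrams(one_hot_pssm(seq)).values
        sb = features.sequence_bigrams(seq).values
        np.testing.assert_allclose(pb, (seq.length - 1) * sb, atol=1e-9)


def test_profile_bigrams_rejects_unnormalized_rows():
    with pytest.raises(FeatureError, match="normalized"):
        features.profile_bigrams(PSSMatrix("i", np.full((3, 20), 0.01)))


def test_profile_bigrams_single_row_is_zero_vector():
    fv = features.profile_bigrams(PSSMatrix("i", np.full((1, 20), 1 / 20)))
    assert fv.values.sum() == 0
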