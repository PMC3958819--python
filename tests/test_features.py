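from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recspot.features import (
    correlation_factors,
    correlation_function,
    encode,
    feature_names,
    kmer_order,
    ktuple_composition,
)
from recspot.physchem import standardized_table
from recspot.seqio import NucleotideSequence
from recspot.translate import AMINO_ACIDS, ProteinSequence, SequenceTooShortError, translate_dna

dna = st.text(alphabet="ACGT", min_size=4, max_size=200)


def brute_force_composition(residues: str, k: int) -> np.ndarray:
    """Independent oracle: dictionary count of overlapping windows."""
    counts = Counter(residues[i : i + k] for i in range(len(residues) - k + 1))
    total = sum(counts.values())
    return np.array([counts.get(m, 0) / total for m in kmer_order(k)])


@pytest.mark.parametrize(
    "residues, k, expected",
    [
        ("ACGT", 1, [0.25, 0.25, 0.25, 0.25]),
        ("AAAA", 3, [1.0] + [0.0] * 63),
        ("ACGT", 3, None),  # checked against the brute-force oracle below
    ],
)
def test_ktuple_examples(residues, k, expected):
    comp = ktuple_composition(NucleotideSequence("x", residues), k)
    if expected is not None:
        assert np.allclose(comp, expected)
    else:
        order = kmer_order(3)
        assert comp[order.index("ACG")] == 0.5
        assert comp[order.index("CGT")] == 0.5
        assert comp.sum() == pytest.approx(1.0)
        assert np.count_nonzero(comp) == 2


@settings(derandomize=True, max_examples=80, deadline=None)
@given(dna, st.integers(min_value=1, max_value=4))
def test_ktuple_matches_brute_force_count(residues, k):
    seq = NucleotideSequence("x", residues)
    assert np.allclose(
        ktuple_composition(seq, k), brute_force_composition(residues, k), atol=1e-12
    )
    assert abs(ktuple_composition(seq, k).sum() - 1) < 1e-12


def test_ktuple_rejects_too_short_sequences():
    with pytest.raises(ValueError):
        ktuple_composition(NucleotideSequence("x", "AC"), 3)


def test_correlation_function_examples():
    rounded = standardized_table(rounded=True)
    assert correlation_function("A", "A") == 0.0
    # hand-sum over the published rounded rows for A and C:
    # ((-0.33)^2+(-0.26)^2+1.03^2+(-3.05)^2+1.80^2+(-0.54)^2)/6 = 14.0715/6
    assert correlation_function("A", "C", rounded) == pytest.approx(
        14.0715 / 6, abs=1e-10
    )


def test_correlation_function_is_symmetric_over_all_400_pairs():
    for a, b in product(AMINO_ACIDS, repeat=2):
        assert correlation_function(a, b) == pytest.approx(
            correlation_function(b, a), abs=1e-12
        )


def test_correlation_function_rejects_unknown_residue():
    with pytest.raises(ValueError, match="unknown amino acid"):
        correlation_function("A", "B")


def test_correlation_factors_of_homogeneous_chain_are_zero():
    prot = translate_dna(NucleotideSequence("x", "A" * 12))  # KKKK
    assert prot.residues == "KKKK"
    assert np.allclose(correlation_factors(prot, 2), 0.0)


def test_single_pair_tier_equals_pair_correlation():
    rounded = standardized_table(rounded=True)
    theta = correlation_factors(ProteinSequence("AC"), 1, rounded)
    assert theta[0] == pytest.approx(correlation_function("A", "C", rounded))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=80))
def test_correlation_factors_match_explicit_loop(chain):
    """Vectorized tiers against a per-position loop oracle."""
    prot = ProteinSequence(chain)
    lam = 5
    table = standardized_table()
    thetas = correlation_factors(prot, lam, table)
    for k in range(1, lam + 1):
        loop = np.mean(
            [
                correlation_function(chain[i], chain[i + k], table)
                for i in range(len(chain) - k)
            ]
        )
        assert thetas[k - 1] == pytest.approx(loop, abs=1e-12)
    assert (thetas >= 0).all()


def test_too_many_tiers_reports_minimum_length():
    prot = ProteinSequence("ACD")
    with pytest.raises(SequenceTooShortError, match="at least 12 nt"):
        correlation_factors(prot, 3)


def test_encode_homopolymer_is_one_hot_in_the_tnc_block():
    vec = encode(NucleotideSequence("x", "A" * 30), lam=5, weight=1.1)
    assert vec[0] == pytest.approx(1.0)  # the AAA component
    assert np.allclose(np.delete(vec, 0), 0.0)


def test_encode_homogeneous_protein_reduces_to_raw_tnc():
    # ACG codons translate to Thr^7: all tiers vanish, TNC passes through
    seq = NucleotideSequence("x", "ACG" * 7)
    vec = encode(seq, lam=2, weight=1.1)
    assert np.allclose(vec[64:], 0.0)
    assert np.allclose(vec[:64], ktuple_composition(seq, 3))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.text(alphabet="ACGT", min_size=60, max_size=300))
def test_encoded_vectors_live_on_the_simplex(residues):
    seq = NucleotideSequence("x", residues)
    try:
        vec = encode(seq, lam=5, weight=1.1)
    except SequenceTooShortError:  # heavy stop-codon loss can shrink L* below lambda
        return
    assert vec.shape == (69,)
    assert (vec >= 0).all()
    assert abs(vec.sum() - 1) < 1e-12


def test_small_weight_limit_recovers_raw_tnc():
    seq = NucleotideSequence("x", "ACGTTGCAGT" * 12)
    tnc = ktuple_composition(seq, 3)
    vec = encode(seq, lam=5, weight=1e-12)
    assert np.allclose(vec[:64], tnc, atol=1e-9)
    assert np.allclose(vec[64:], 0.0, atol=1e-9)


def test_encode_is_deterministic_bitwise():
    seq = NucleotideSequence("x", "ACGTTGCAGT" * 30)
    a = encode(seq)
    b = encode(seq)
    assert (a == b).all()


def test_encode_rejects_nonpositive_weight():
    with pytest.raises(ValueError, match="weight"):
        encode(NucleotideSequence("x", "ACGT" * 20), weight=0.0)


def test_feature_names_schema():
    names = feature_names(5)
    assert len(names) == 69
    assert names[0] == "AAA" and names[63] == "TTT"
    assert names[64:] == [f"theta_{k}" for k in range(1, 6)]
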