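"""Sequence encoding: K-tuple nucleotide composition + PseAAC correlation tiers.

A DNA sequence of length L is represented by

* the 64 trinucleotide composition (TNC) frequencies ``f_u``, counted over
  all L-2 overlapping windows in lexicographic k-mer order (AAA, AAC, ...,
  TTT), normalized to sum to 1; and
* ``lambda`` correlation factors ``theta_k`` of its translated, stop-free
  protein chain: ``theta_k`` is the average over positions i of the mean
  squared difference of six standardized physicochemical properties
  between residues i and i+k.  These tiers inject long-range order
  information the composition alone cannot carry.

The combined vector has components

    d_u = f_u / (1 + w * sum(theta)),            u = 1..64
    d_{64+k} = w * theta_k / (1 + w * sum(theta)), k = 1..lambda

(using sum(f) = 1), so every encoded vector lies on the probability
simplex.  Defaults lambda=5, weight w=1.1.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from recspot.physchem import PropertyTable, standardized_table
from recspot.seqio import NucleotideSequence
from recspot.translate import ProteinSequence, SequenceTooShortError, translate_dna

DEFAULT_LAMBDA = 5
DEFAULT_WEIGHT = 1.1

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_MAX_K = 6


@lru_cache(maxsize=None)
def kmer_order(k: int = 3) -> tuple[str, ...]:
    """Lexicographic ordering of the 4**k k-mers over A < C < G < T."""
    return tuple("".join(p) for p in product("ACGT", repeat=k))


def ktuple_composition(seq: NucleotideSequence, k: int = 3) -> np.ndarray:
    """Normalized K-tuple (k-mer) composition of a DNA sequence.

    Counts all L-k+1 overlapping windows and divides by the window count,
    so the returned vector of length 4**k sums to 1.  K=1 is the
    mononucleotide composition (MNC), K=2 the dinucleotide (DNC), K=3 the
    trinucleotide (TNC).
    """
    if not 1 <= k <= _MAX_K:
        raise ValueError(f"k must be in 1..{_MAX_K}, got {k}")
    L = seq.length
    if L < k:
        raise ValueError(f"sequence length {L} shorter than tuple size {k}")
    codes = np.fromiter((_BASE_INDEX[c] for c in seq.residues), dtype=np.int64, count=L)
    idx = np.zeros(L - k + 1, dtype=np.int64)
    for offset in range(k):
        idx = idx * 4 + codes[offset : L - k + 1 + offset]
    counts = np.bincount(idx, minlength=4**k)
    return counts / counts.sum()


def _property_matrix(table: PropertyTable) -> pd.DataFrame:
    if not table.standardized:
        raise ValueError("property table must be standardized")
    return table.values


def correlation_function(a: str, b: str, table: Optional[PropertyTable] = None) -> float:
    """Mean squared property difference Theta(a, b) between two amino acids.

    Theta(a, b) = (1/6) * sum_n [H_n(b) - H_n(a)]^2 over the six
    standardized physicochemical properties.  Symmetric; zero iff the two
    property rows are identical.
    """
    df = _property_matrix(table if table is not None else standardized_table())
    try:
        ha = df.loc[a].to_numpy()
        hb = df.loc[b].to_numpy()
    except KeyError as exc:
        raise ValueError(f"unknown amino acid code: {exc.args[0]!r}") from None
    return float(np.mean((hb - ha) ** 2))


def correlation_factors(
    prot: ProteinSequence, lam: int, table: Optional[PropertyTable] = None
) -> np.ndarray:
    """The first ``lam`` sequence-order correlation tiers of a protein chain.

    theta_k = (1/(L*-k)) * sum_{i=1}^{L*-k} Theta(A_i, A_{i+k}), where L*
    is the stop-free chain length.  Requires lam < L*.
    """
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    L_star = prot.length
    if lam >= L_star:
        raise SequenceTooShortError(
            f"sequence too short for {lam} correlation tiers: stop-free chain "
            f"length {L_star} must exceed lambda (DNA length of at least "
            f"{3 * (lam + 1)} nt is required, more if stop codons occur)"
        )
    df = _property_matrix(table if table is not None else standardized_table())
    H = df.loc[list(prot.residues)].to_numpy()  # (L*, 6)
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diff = H[k:] - H[:-k]
        thetas[k - 1] = np.mean(diff**2)  # averages over both positions and the 6 properties
    return thetas


def encode(
    seq: NucleotideSequence,
    lam: int = DEFAULT_LAMBDA,
    weight: float = DEFAULT_WEIGHT,
    table: Optional[PropertyTable] = None,
) -> np.ndarray:
    """Encode a DNA sequence as the combined 64+lambda feature vector.

    The first 64 components are the TNC frequencies, the last ``lam`` the
    weighted correlation tiers, all divided by the shared normalizer
    ``1 + weight * sum(theta)`` so the vector sums to 1.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    tnc = ktuple_composition(seq, 3)
    prot = translate_dna(seq)
    thetas = correlation_factors(prot, lam, table)
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([tnc, weight * thetas]) / denom


def feature_names(lam: int = DEFAULT_LAMBDA) -> list[str]:
    """Column names for the encoded vector: AAA..TTT, theta_1..theta_lam."""
    return list(kmer_order(3)) + [f"theta_{k}" for k in range(1, lam + 1)]


def encode_many(
    seqs: Iterable[NucleotideSequence],
    lam: int = DEFAULT_LAMBDA,
    weight: float = DEFAULT_WEIGHT,
    table: Optional[PropertyTable] = None,
) -> pd.DataFrame:
    """Encode a collection of sequences into a feature matrix.

    Returns a DataFrame indexed by sequence id with 64+lam named columns;
    ``.to_numpy()`` gives the dense matrix for model training.
    """
    seqs = list(seqs)
    X = np.empty((len(seqs), 64 + lam))
    for i, s in enumerate(seqs):
        X[i] = encode(s, lam=lam, weight=weight, table=table)
    return pd.DataFrame(
        X, index=pd.Index([s.id for s in seqs], name="id"), columns=feature_names(lam)
    )
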