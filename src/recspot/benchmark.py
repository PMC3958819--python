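"""Reproduction of the published hotspot/coldspot benchmark evaluation.

The benchmark is a curated yeast dataset of 490 recombination hotspot and
591 coldspot sequences distributed as supplementary material with the
original predictor's web server; it is not redistributed with this
package.  To reproduce the published jackknife figures, supply the two
FASTA files (one per class) and call :func:`reproduce`, which encodes
every sequence with the default parameters (lambda=5, w=1.1), runs the
full leave-one-out jackknife at C=32, gamma=0.5, and returns the metric
set.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from recspot.classifier import COLDSPOT, DEFAULT_C, DEFAULT_GAMMA, HOTSPOT
from recspot.evaluation import EvaluationResult, jackknife
from recspot.features import DEFAULT_LAMBDA, DEFAULT_WEIGHT, encode_many
from recspot.seqio import read_fasta


def load_benchmark(
    hotspot_fasta: Union[str, Path], coldspot_fasta: Union[str, Path]
):
    """Load the two benchmark FASTA files into sequences + labels."""
    hot = read_fasta(hotspot_fasta)
    cold = read_fasta(coldspot_fasta)
    if not hot or not cold:
        raise ValueError("both benchmark classes must be nonempty")
    seqs = hot + cold
    labels = [HOTSPOT] * len(hot) + [COLDSPOT] * len(cold)
    return seqs, labels


def reproduce(
    hotspot_fasta: Union[str, Path],
    coldspot_fasta: Union[str, Path],
    lam: int = DEFAULT_LAMBDA,
    weight: float = DEFAULT_WEIGHT,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> EvaluationResult:
    """Full jackknife on a user-supplied benchmark at the published settings."""
    seqs, labels = load_benchmark(hotspot_fasta, coldspot_fasta)
    features = encode_many(seqs, lam=lam, weight=weight)
    return jackknife(
        features.to_numpy(), labels, C=C, gamma=gamma, ids=list(features.index)
    )
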