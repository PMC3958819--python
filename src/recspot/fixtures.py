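"""Synthetic two-class DNA datasets with controllable composition signal.

The generator emulates a hotspot/coldspot benchmark: two sets of genomic
windows whose classes differ in base composition.  Each class is sampled
from its own first-order Markov chain over {A, C, G, T}; the stationary
base frequencies are set by the class GC content (A/T and C/G split
evenly), and a ``persistence`` parameter blends the transition rows toward
self-transition, injecting dinucleotide/trinucleotide structure beyond
what mononucleotide content dictates.  Lengths are uniform over a range
defaulting to 300-3000 nt, the scale on which recombination events
concentrate (roughly 1-2.5 kb windows).

Identical spec + seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from recspot.classifier import COLDSPOT, HOTSPOT
from recspot.seqio import NucleotideSequence

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-class dataset.

    Attributes
    ----------
    n_per_class : int
        Sequences per class.
    length_range : (int, int)
        Inclusive bounds on sequence length; the minimum must allow the
        pseudo-composition of the intended lambda even after stop-codon
        loss, i.e. be at least ``9 * (lambda_max + 1)``.
    gc_hot, gc_cold : float
        GC content of the hotspot / coldspot class in (0, 1).
    persistence_hot, persistence_cold : float
        Markov self-transition blend in [0, 1); 0 gives i.i.d. bases.
    lambda_max : int
        Largest correlation-tier count the dataset must support.
    seed : int
        Seed for the random generator.
    """

    n_per_class: int = 30
    length_range: tuple[int, int] = (300, 3000)
    gc_hot: float = 0.5
    gc_cold: float = 0.5
    persistence_hot: float = 0.0
    persistence_cold: float = 0.0
    lambda_max: int = 5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        min_required = 3 * (self.lambda_max + 1) * 3
        if lo > hi:
            raise ValueError(f"infeasible length range {self.length_range}")
        if lo < min_required:
            raise ValueError(
                f"minimum length {lo} too short: need >= {min_required} nt so "
                f"{self.lambda_max} correlation tiers survive stop-codon loss"
            )
        for name in ("gc_hot", "gc_cold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("persistence_hot", "persistence_cold"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def _transition_matrix(gc: float, persistence: float) -> np.ndarray:
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return (1 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)


def _sample_sequence(rng: np.random.Generator, length: int, gc: float,
                     persistence: float) -> str:
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = _transition_matrix(gc, persistence)
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(4, p=pi)
    # cumulative rows let every step reuse one uniform draw
    cum = T.cumsum(axis=1)
    u = rng.random(length - 1)
    for i in range(1, length):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    return "".join(_BASES[states])


def generate(spec: FixtureSpec) -> tuple[list[NucleotideSequence], np.ndarray]:
    """Generate a labeled two-class dataset from a spec.

    Returns ``(sequences, labels)`` with labels +1 (hotspot) for the first
    ``n_per_class`` sequences and -1 (coldspot) for the rest.
    Deterministic per spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    seqs: list[NucleotideSequence] = []
    labels: list[int] = []
    for label, prefix, gc, pers in (
        (HOTSPOT, "hot", spec.gc_hot, spec.persistence_hot),
        (COLDSPOT, "cold", spec.gc_cold, spec.persistence_cold),
    ):
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            residues = _sample_sequence(rng, length, gc, pers)
            seqs.append(NucleotideSequence(id=f"{prefix}_{i + 1:04d}", residues=residues))
            labels.append(label)
    return seqs, np.array(labels, dtype=int)


def write_labels(labels_by_id: dict[str, int], sink: Union[str, Path]) -> None:
    """Write a two-column (id, label) TSV; labels are +1 / -1."""
    with open(sink, "w") as fh:
        fh.write("id\tlabel\n")
        for sid, label in labels_by_id.items():
            fh.write(f"{sid}\t{label}\n")


def read_labels(source: Union[str, Path]) -> dict[str, int]:
    """Read the (id, label) TSV written by :func:`write_labels`."""
    out: dict[str, int] = {}
    lines = Path(source).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, label = line.split("\t")
        out[sid] = int(label)
    return out
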