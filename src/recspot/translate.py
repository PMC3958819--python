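"""Codon translation of DNA into an amino acid chain.

The sequence is read in frame 0 on the given strand in non-overlapping
triplets; 1-2 trailing nucleotides beyond the last full codon are
discarded, so the raw codon count is Int{L/3}.  The three stop codons
(TAA, TAG, TGA) map to no amino acid: because the inputs are genomic
windows rather than open reading frames, stops are removed from the chain
(not used to truncate it) and the downstream pseudo-composition is computed
over the stop-free chain as if it were contiguous.  The effective chain
length L* is therefore Int{L/3} minus the number of stops encountered.
"""

from __future__ import annotations

from dataclasses import dataclass

from recspot.seqio import NucleotideSequence

#: Marker used for the three stop codons in the codon table.
STOP = "*"

# Standard genetic code, keyed by DNA codon.
_CODON_TABLE: dict[str, str] = {
    "AAA": "K", "AAC": "N", "AAG": "K", "AAT": "N",
    "ACA": "T", "ACC": "T", "ACG": "T", "ACT": "T",
    "AGA": "R", "AGC": "S", "AGG": "R", "AGT": "S",
    "ATA": "I", "ATC": "I", "ATG": "M", "ATT": "I",
    "CAA": "Q", "CAC": "H", "CAG": "Q", "CAT": "H",
    "CCA": "P", "CCC": "P", "CCG": "P", "CCT": "P",
    "CGA": "R", "CGC": "R", "CGG": "R", "CGT": "R",
    "CTA": "L", "CTC": "L", "CTG": "L", "CTT": "L",
    "GAA": "E", "GAC": "D", "GAG": "E", "GAT": "D",
    "GCA": "A", "GCC": "A", "GCG": "A", "GCT": "A",
    "GGA": "G", "GGC": "G", "GGG": "G", "GGT": "G",
    "GTA": "V", "GTC": "V", "GTG": "V", "GTT": "V",
    "TAA": STOP, "TAC": "Y", "TAG": STOP, "TAT": "Y",
    "TCA": "S", "TCC": "S", "TCG": "S", "TCT": "S",
    "TGA": STOP, "TGC": "C", "TGG": "W", "TGT": "C",
    "TTA": "L", "TTC": "F", "TTG": "L", "TTT": "F",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SequenceTooShortError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    """Translated amino acid chain with stop codons removed.

    Attributes
    ----------
    residues : str
        One-letter codes over the 20 native amino acids; no stop symbol.
    n_stops_removed : int
        How many stop codons were dropped during translation.
    """

    residues: str
    n_stops_removed: int = 0

    def __post_init__(self):
        for ch in self.residues:
            if ch not in AMINO_ACIDS:
                raise ValueError(f"not a native amino acid code: {ch!r}")

    @property
    def length(self) -> int:
        """Effective (stop-free) chain length L*."""
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def codon_table() -> dict[str, str]:
    """The 64-codon conversion table (DNA codons to one-letter amino acids).

    Stop codons TAA, TAG, TGA map to :data:`STOP`.  Returns a copy.
    """
    return dict(_CODON_TABLE)


def translate_dna(seq: NucleotideSequence) -> ProteinSequence:
    """Translate a DNA sequence into its stop-free amino acid chain.

    Raises
    ------
    SequenceTooShortError
        If the sequence is shorter than one codon (L < 3).
    """
    dna = seq.residues
    if len(dna) < 3:
        raise SequenceTooShortError(
            f"record {seq.id!r}: sequence shorter than one codon (L={len(dna)})"
        )
    n_codons = len(dna) // 3
    chain = []
    n_stops = 0
    for i in range(n_codons):
        aa = _CODON_TABLE[dna[3 * i : 3 * i + 3]]
        if aa == STOP:
            n_stops += 1
        else:
            chain.append(aa)
    return ProteinSequence(residues="".join(chain), n_stops_removed=n_stops)
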