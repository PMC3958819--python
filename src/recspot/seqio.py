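"""FASTA input/output with a strict A/C/G/T alphabet contract.

Sequences are validated on construction: after upcasing and whitespace
removal every residue must be one of A, C, G, T.  Ambiguity codes such as
N are rejected rather than skipped, because a single undefined nucleotide
corrupts every overlapping trinucleotide window and every translated codon
it touches.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

Source = Union[str, Path, TextIO]


class FastaParseError(ValueError):
    """Structurally malformed FASTA (e.g. sequence data before any header)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class InvalidSequenceError(ValueError):
    """A record contains characters outside the A/C/G/T alphabet."""

    def __init__(self, record_id: str, bad_char: str):
        self.record_id = record_id
        self.bad_char = bad_char
        super().__init__(
            f"record {record_id!r} contains invalid character {bad_char!r}; "
            "only A, C, G, T are accepted"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over {A, C, G, T}.

    Parameters
    ----------
    id : str
        Free-text identifier (FASTA header word).
    residues : str
        Nucleotide string; upcased and whitespace-stripped on construction.
    """

    id: str
    residues: str

    def __post_init__(self):
        cleaned = "".join(self.residues.split()).upper()
        object.__setattr__(self, "residues", cleaned)
        if len(cleaned) < 1:
            raise InvalidSequenceError(self.id, "<empty>")
        for ch in cleaned:
            if ch not in DNA_ALPHABET:
                raise InvalidSequenceError(self.id, ch)

    @property
    def length(self) -> int:
        """Number of nucleotides L."""
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _as_text(source: Source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def read_fasta(source: Source, errors: str = "raise"):
    """Read DNA sequences from a FASTA file or text stream.

    Parameters
    ----------
    source : path or text stream
    errors : {"raise", "collect"}
        With ``"raise"`` (default) the first invalid record aborts the read.
        With ``"collect"`` invalid records are reported alongside the valid
        ones, mirroring a batch server that processes what it can: returns
        ``(records, rejected)`` where ``rejected`` is a list of
        :class:`InvalidSequenceError`.

    Returns
    -------
    list of NucleotideSequence, or ``(records, rejected)`` when
    ``errors="collect"``.

    Raises
    ------
    FastaParseError
        If sequence data precedes any ``>`` header (names the line).
    InvalidSequenceError
        With ``errors="raise"``, on the first record containing a character
        outside {A, C, G, T}.
    """
    if errors not in {"raise", "collect"}:
        raise ValueError(f"errors must be 'raise' or 'collect', got {errors!r}")
    text = _as_text(source)
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError("sequence data before any FASTA header", line=lineno)
        break

    records: list[NucleotideSequence] = []
    rejected: list[InvalidSequenceError] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen_ids:
            warnings.warn(f"duplicate FASTA id {rec.id!r}", stacklevel=2)
        seen_ids.add(rec.id)
        try:
            records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
        except InvalidSequenceError as exc:
            if errors == "raise":
                raise
            rejected.append(exc)
    if errors == "collect":
        return records, rejected
    return records


def write_fasta(records: Iterable[NucleotideSequence], sink: Source) -> None:
    """Write records as multi-FASTA, sequence lines wrapped at 60 columns.

    Round-trip contract: ``read_fasta`` on the output reproduces ids and
    residues exactly.
    """
    seq_records = [
        SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in records
    ]
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as handle:
            SeqIO.write(seq_records, handle, "fasta")
    else:
        SeqIO.write(seq_records, sink, "fasta")
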