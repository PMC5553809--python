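"""Genome sequences on circular (bacterial) or linear coordinate systems."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Nucleotides accepted by the exact-match machinery.
DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A named nucleotide sequence with circular/linear topology.

    Coordinates are 0-based half-open throughout the package. On a circular
    genome, positions are taken modulo ``len(genome)`` and fetches may wrap
    the origin.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_alphabet(self) -> None:
        """Raise ``ValueError`` if the sequence contains non-ACGT characters."""
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r} contains non-ACGT characters: {sorted(bad)}")

    def fetch(self, start: int, length: int) -> str:
        """Substring of ``length`` bases starting at ``start`` (wraps if circular)."""
        g = len(self.sequence)
        if length > g:
            raise ValueError("fetch longer than genome")
        if self.circular:
            start %= g
            end = start + length
            if end <= g:
                return self.sequence[start:end]
            return self.sequence[start:] + self.sequence[: end - g]
        if start < 0 or start + length > g:
            raise IndexError("fetch outside linear genome")
        return self.sequence[start : start + length]

    @classmethod
    def from_fasta(cls, path: str | Path, circular: bool = True) -> "Genome":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=record.id, sequence=str(record.seq), circular=circular)

    def to_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.id, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")
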