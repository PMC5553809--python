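"""Quality filtering and length standardization of sequencing reads.

The anchoring stage requires fixed-length reads with exact genome
correspondence, so libraries are (a) filtered on a per-base Phred floor and
(b) center-trimmed to a standard length (50 nt by default), discarding reads
that are shorter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Read:
    """One read: id, sequence, optional per-base Phred qualities.

    Plain ``__slots__`` class (libraries hold millions of these).
    """

    __slots__ = ("id", "sequence", "quality")

    def __init__(self, id: str, sequence: str, quality: Sequence[int] | None = None):
        if quality is not None and len(quality) != len(sequence):
            raise ValueError(f"read {id!r}: sequence/quality length mismatch")
        self.id = id
        self.sequence = sequence
        self.quality = quality

    def __repr__(self) -> str:
        return f"Read(id={self.id!r}, len={len(self.sequence)})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Read):
            return NotImplemented
        return (self.id, self.sequence, list(self.quality or [])) == (
            other.id, other.sequence, list(other.quality or [])
        )


@dataclass
class ReadLibrary:
    """A list of reads plus provenance (``control`` or ``ip``, experiment id)."""

    reads: list[Read] = field(default_factory=list)
    label: str = "control"
    experiment: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_fastq(cls, path: str | Path, label: str = "control", experiment: str = "") -> "ReadLibrary":
        reads = [
            Read(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
            for rec in SeqIO.parse(str(path), "fastq")
        ]
        return cls(reads, label=label, experiment=experiment)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
                qual = r.quality if r.quality is not None else [40] * len(r.sequence)
                rec.letter_annotations["phred_quality"] = list(qual)
                SeqIO.write([rec], fh, "fastq")


@dataclass
class PrepReport:
    """Retained/discarded tallies from a filtering or trimming pass."""

    retained: int
    discarded: int

    def to_tsv_row(self, stage: str) -> str:
        return f"{stage}\t{self.retained}\t{self.discarded}"


def quality_filter(
    lib: ReadLibrary, q_min: int = 20, require_quality: bool = True
) -> tuple[ReadLibrary, PrepReport]:
    """Keep exactly the reads whose *every* base has Phred quality >= ``q_min``.

    Order is preserved.  Reads without qualities raise unless
    ``require_quality`` is False, in which case they pass through untouched.
    """
    kept: list[Read] = []
    for r in lib.reads:
        if r.quality is None:
            if require_quality:
                raise ValueError(f"read {r.id!r} has no quality values")
            kept.append(r)
        elif len(r.quality) == 0 or min(r.quality) >= q_min:
            kept.append(r)
    report = PrepReport(retained=len(kept), discarded=len(lib) - len(kept))
    return ReadLibrary(kept, label=lib.label, experiment=lib.experiment), report


def trim_to_center(lib: ReadLibrary, target: int = 50) -> tuple[ReadLibrary, PrepReport]:
    """Standardize read length by taking the central ``target``-length substring.

    Reads shorter than ``target`` are discarded.  With an odd surplus the left
    offset is ``floor((len - target) / 2)``.  Qualities are trimmed with the
    same slice.
    """
    if target < 1:
        raise ValueError("target length must be >= 1")
    kept: list[Read] = []
    for r in lib.reads:
        n = len(r.sequence)
        if n < target:
            continue
        if n == target:
            kept.append(r)
            continue
        off = (n - target) // 2
        qual = None if r.quality is None else list(r.quality[off : off + target])
        kept.append(Read(r.id, r.sequence[off : off + target], qual))
    report = PrepReport(retained=len(kept), discarded=len(lib) - len(kept))
    return ReadLibrary(kept, label=lib.label, experiment=lib.experiment), report
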