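"""Exact-match, strand-collapsed read anchoring.

Each fixed-length read is matched against both genome strands with *no*
mismatches allowed.  The anchor coordinate is always the left (smaller)
genome position of the matching window, so a read and its exact reverse
complement contribute to the same position: top-strand reads are anchored at
their 5' end, bottom-strand reads at their 3' end.  Multi-locus reads are
either counted at every locus (``all-occurrences``, default) or dropped
(``unique-only``).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import Genome, reverse_complement
from .read_prep import ReadLibrary

POLICIES = ("all-occurrences", "unique-only")


class ExactIndex:
    """Hash index of every ``read_length``-mer of the genome's top strand.

    On a circular genome the k-mers spanning the origin are included, so the
    left coordinate ranges over all ``G`` positions.  Lookup is strand
    collapsed: a query hits position ``p`` if either the query or its reverse
    complement equals the top-strand window at ``p``.
    """

    def __init__(self, genome: Genome, read_length: int) -> None:
        if read_length > len(genome):
            raise ValueError("read_length exceeds genome length")
        genome.validate_alphabet()
        self.genome_id = genome.id
        self.genome_length = len(genome)
        self.read_length = read_length
        seq = genome.sequence
        if genome.circular:
            ext = seq + seq[: read_length - 1]
            n_pos = len(seq)
        else:
            ext = seq
            n_pos = len(seq) - read_length + 1
        index: dict[str, list[int]] = defaultdict(list)
        for p in range(n_pos):
            index[ext[p : p + read_length]].append(p)
        self._index = dict(index)

    def lookup(self, seq: str) -> list[int]:
        """All left coordinates where ``seq`` matches either strand exactly."""
        if len(seq) != self.read_length:
            raise ValueError(
                f"query length {len(seq)} != index read length {self.read_length}"
            )
        fwd = self._index.get(seq, ())
        rc = reverse_complement(seq)
        if rc == seq:  # a self-complementary read is one molecule: count once
            return list(fwd)
        rev = self._index.get(rc, ())
        if not rev:
            return list(fwd)
        if not fwd:
            return list(rev)
        return sorted(set(fwd) | set(rev))


@dataclass
class AnchorProfile:
    """Per-position anchored-read counts for one library."""

    genome_id: str
    counts: np.ndarray  # length G
    policy: str = "all-occurrences"
    n_anchored: int = 0
    n_unanchored: int = 0
    n_multi: int = 0
    label: str = ""
    circular: bool = True

    @property
    def genome_length(self) -> int:
        return len(self.counts)

    def to_bedgraph(self, path: str | Path) -> None:
        write_bedgraph(path, self.genome_id or "genome", self.counts)

    def summary_tsv(self) -> str:
        return (
            "policy\tn_anchored\tn_unanchored\tn_multi\n"
            f"{self.policy}\t{self.n_anchored}\t{self.n_unanchored}\t{self.n_multi}\n"
        )


def write_bedgraph(path, chrom: str, values: np.ndarray) -> None:
    """Write a per-position track as bedGraph runs (0-based half-open)."""
    values = np.asarray(values)
    n = len(values)
    breaks = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            txt = f"{v:.6g}" if isinstance(v, (float, np.floating)) else str(int(v))
            fh.write(f"{chrom}\t{s}\t{e}\t{txt}\n")


def read_bedgraph(path, genome_length: int) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    out = np.zeros(genome_length, dtype=float)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        out[s:e] = v
    return out


def build_index(genome: Genome, read_length: int) -> ExactIndex:
    """Build the exact-lookup index (function-style alias for ``ExactIndex``)."""
    return ExactIndex(genome, read_length)


def anchor_reads(
    lib: ReadLibrary, index: ExactIndex, policy: str = "all-occurrences"
) -> AnchorProfile:
    """Anchor every read of ``lib`` and accumulate per-position counts.

    ``all-occurrences``: a read matching k loci adds 1 at each locus.
    ``unique-only``: multi-locus reads are dropped and tallied in ``n_multi``.
    Reads with no exact match on either strand (including any read containing
    N) are tallied in ``n_unanchored``.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    counts = np.zeros(index.genome_length, dtype=np.int64)
    n_anchored = n_unanchored = n_multi = 0
    L = index.read_length
    for r in lib.reads:
        if len(r.sequence) != L:
            raise ValueError(
                f"read {r.id!r} length {len(r.sequence)} != index read length {L}"
            )
        loci = index.lookup(r.sequence)
        if not loci:
            n_unanchored += 1
        elif len(loci) == 1:
            counts[loci[0]] += 1
            n_anchored += 1
        else:
            n_multi += 1
            if policy == "all-occurrences":
                for p in loci:
                    counts[p] += 1
                n_anchored += 1
    return AnchorProfile(
        genome_id=index.genome_id,
        counts=counts,
        policy=policy,
        n_anchored=n_anchored,
        n_unanchored=n_unanchored,
        n_multi=n_multi,
        label=lib.label,
    )
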