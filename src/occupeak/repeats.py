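"""Direct and inverted repeat-pair scanning.

A repeat pair with arm length ``i`` and spacer ``j`` at top-strand position
``p`` consists of the arm ``genome[p : p+i]`` followed, after exactly ``j``
intervening bases, by a second arm that is an identical copy (direct) or the
reverse complement of the first (inverted).  The pair's *footprint* is the
holistic unit ``[p, p + 2i + j)`` of length ``2i + j``.  Each qualifying
``(position, i, j)`` triple is counted once, identified by its leftmost
coordinate; an inverted pair is its own mirror image, so scanning the top
strand enumerates every pair exactly once.

Scanning is vectorized: for a direct pair the base-match track
``genome[p] == genome[p + i + j]`` is a single circular shift, and arm
matches are windows where the match track holds ``i`` times in a row.  For
an inverted pair the paired indices sum to the constant ``2p + 2i + j - 1``,
so each of the ``i`` base comparisons is again a fixed shift of the genome
against its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .genome import Genome

REPEAT_TYPES = ("direct", "inverted")

#: Study-default scan ranges: direct 5-24 bp arms / 0-20 bp spacers,
#: inverted 5-18 bp arms / 3-20 bp spacers.
DEFAULT_RANGES = {
    "direct": (range(5, 25), range(0, 21)),
    "inverted": (range(5, 19), range(3, 21)),
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class RepeatPair:
    type: str
    i: int
    j: int
    start: int

    @property
    def footprint(self) -> tuple[int, int]:
        """(start, start + 2i + j); may extend past G on a circular genome."""
        return self.start, self.start + 2 * self.i + self.j


@dataclass
class RepeatCatalog:
    """Repeat pairs grouped by (type, arm length i, spacer j)."""

    genome_id: str
    genome_length: int
    positions: dict[tuple[str, int, int], np.ndarray] = field(default_factory=dict)

    def add(self, rtype: str, i: int, j: int, starts: np.ndarray) -> None:
        self.positions[(rtype, i, j)] = np.sort(np.asarray(starts, dtype=np.int64))

    def count(self, rtype: str, i: int, j: int) -> int:
        return len(self.positions.get((rtype, i, j), ()))

    def pairs(self, rtype: str, i: int, j: int) -> list[RepeatPair]:
        return [
            RepeatPair(rtype, i, j, int(p))
            for p in self.positions.get((rtype, i, j), ())
        ]

    def footprints(self, rtype: str, i: int, j: int) -> np.ndarray:
        """(n, 2) array of [start, end) footprints (ends may exceed G: wrap)."""
        starts = self.positions.get((rtype, i, j), np.empty(0, dtype=np.int64))
        span = 2 * i + j
        return np.column_stack([starts, starts + span])

    def totals(self, rtype: str, i: int, j: int) -> tuple[int, int]:
        """(n_ij, L_ij) with L_ij = n_ij * (2i + j): summed footprint length
        under the multiplicity convention (overlaps not merged)."""
        n = self.count(rtype, i, j)
        return n, n * (2 * i + j)

    def summary_tsv(self) -> str:
        lines = ["type\ti\tj\tn\ttotal_bp"]
        for (t, i, j) in sorted(self.positions):
            n, L = self.totals(t, i, j)
            lines.append(f"{t}\t{i}\t{j}\t{n}\t{L}")
        return "\n".join(lines) + "\n"

    def pairs_tsv(self) -> str:
        lines = ["type\ti\tj\tstart\tfootprint_len"]
        for (t, i, j) in sorted(self.positions):
            for p in self.positions[(t, i, j)]:
                lines.append(f"{t}\t{i}\t{j}\t{int(p)}\t{2 * i + j}")
        return "\n".join(lines) + "\n"


def _encode(genome: Genome) -> np.ndarray:
    genome.validate_alphabet()
    return np.frombuffer(
        genome.sequence.encode().translate(
            bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
        ),
        dtype=np.uint8,
    )


def _match_positions(
    code: np.ndarray, comp: np.ndarray, rtype: str, i: int, j: int, circular: bool
) -> np.ndarray:
    n = len(code)
    if rtype == "direct":
        base = code == np.roll(code, -(i + j))
        cs = np.concatenate([[0], np.cumsum(np.concatenate([base, base[: i - 1]]))])
        ok = (cs[i:] - cs[:-i])[:n] == i
    else:
        ok = np.ones(n, dtype=bool)
        shift_sum = 2 * i + j - 1  # paired index offsets sum to this constant
        for k in range(i):
            ok &= np.roll(code, -k) == np.roll(comp, -(shift_sum - k))
    if not circular:
        span = 2 * i + j
        if span > n:
            return np.empty(0, dtype=np.int64)
        ok[n - span + 1 :] = False
    return np.flatnonzero(ok).astype(np.int64)


def _extendable(
    code: np.ndarray, comp: np.ndarray, rtype: str, i: int, j: int,
    starts: np.ndarray, circular: bool
) -> np.ndarray:
    """Mask of pairs extendable to a longer qualifying pair at the same center
    (arm +1 outward keeping the spacer, or inward into the spacer)."""
    n = len(code)
    p = starts
    ext = np.zeros(len(p), dtype=bool)

    def at(idx):
        return code[np.mod(idx, n)]

    def cat(idx):
        return comp[np.mod(idx, n)]

    if rtype == "direct":
        # arm extension preserves the alignment offset d and eats the spacer,
        # so it exists only for j >= 1: (p-1, i+1, j-1) or (p, i+1, j-1)
        if j >= 1:
            d = i + j
            left = at(p - 1) == at(p - 1 + d)
            right = at(p + i) == at(p + i + d)
            if not circular:
                left &= p - 1 >= 0
                right &= p + 2 * i + j < n
            ext = left | right
    else:
        outward = at(p - 1) == cat(p + 2 * i + j)  # -> (p-1, i+1, j)
        if not circular:
            outward &= (p - 1 >= 0) & (p + 2 * i + j < n)
        ext = outward
        if j >= 2:  # inward -> (p, i+1, j-2)
            ext = ext | (at(p + i) == cat(p + i + j - 1))
    return ext


def scan_repeats(
    genome: Genome,
    rtype: str = "inverted",
    i_range: Iterable[int] | None = None,
    j_range: Iterable[int] | None = None,
    maximality: str = "none",
) -> RepeatCatalog:
    """Enumerate repeat pairs for every (i, j) in the given ranges.

    ``maximality='none'`` (default) counts every qualifying (position, i, j);
    ``'arm-maximal'`` suppresses pairs whose arms can be extended by one base
    (outward or into the spacer) to a longer qualifying pair at the same
    center.
    """
    if rtype not in REPEAT_TYPES:
        raise ValueError(f"unknown repeat type {rtype!r}")
    if maximality not in ("none", "arm-maximal"):
        raise ValueError(f"unknown maximality {maximality!r}")
    default_i, default_j = DEFAULT_RANGES[rtype]
    i_range = list(i_range if i_range is not None else default_i)
    j_range = list(j_range if j_range is not None else default_j)
    if not i_range or not j_range:
        raise ValueError("empty i_range or j_range")
    if min(i_range) < 1 or min(j_range) < 0:
        raise ValueError("require i >= 1 and j >= 0")
    code = _encode(genome)
    comp = 3 - code  # A<->T, C<->G under the 2-bit coding
    cat = RepeatCatalog(genome_id=genome.id, genome_length=len(genome))
    for i in i_range:
        for j in j_range:
            if 2 * i + j > len(genome):
                cat.add(rtype, i, j, np.empty(0, dtype=np.int64))
                continue
            starts = _match_positions(code, comp, rtype, i, j, genome.circular)
            if maximality == "arm-maximal" and len(starts):
                ext = _extendable(code, comp, rtype, i, j, starts, genome.circular)
                starts = starts[~ext]
            cat.add(rtype, i, j, starts)
    return cat


def catalog_totals(cat: RepeatCatalog, rtype: str, i: int, j: int) -> tuple[int, int]:
    """(count, summed footprint bp) for one (type, i, j) cell; (0, 0) if absent."""
    return cat.totals(rtype, i, j)
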