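"""Sorted, disjoint genomic interval sets with 0-based half-open coordinates.

This is the pipeline's currency for peaks, unbound regions and external
annotation sets.  All coordinates live on the linear frame ``[0, G)``; an
element that wraps the replication origin of a circular genome is represented
by its two linear pieces (helpers in :mod:`occupeak.enrichment` split wrapped
footprints before they reach an ``IntervalSet``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class IntervalSet:
    """Immutable normalized set of intervals: sorted, pairwise disjoint.

    Parameters
    ----------
    intervals:
        Iterable of ``(start, end)`` pairs, ``start < end``.  Overlapping or
        bookended input intervals are merged during normalization (union
        semantics).
    genome_id, genome_length:
        Optional provenance; ``genome_length`` enables bounds checking and
        genome-fraction computations.
    label:
        Free-text provenance tag (``peaks-exp1``, ``CS``, ``UR`` ...).
    """

    def __init__(
        self,
        intervals: Iterable[Sequence[int]] = (),
        genome_id: str = "",
        genome_length: int | None = None,
        label: str = "",
    ) -> None:
        arr = np.asarray(list(intervals), dtype=np.int64)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("intervals must be (start, end) pairs")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("empty or inverted interval")
        if genome_length is not None and arr.size and (
            arr[:, 0].min() < 0 or arr[:, 1].max() > genome_length
        ):
            raise ValueError("interval outside [0, genome_length)")
        self.starts, self.ends = self._normalize(arr)
        self.genome_id = genome_id
        self.genome_length = genome_length
        self.label = label

    @staticmethod
    def _normalize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(arr) == 0:
            return arr[:, 0].copy(), arr[:, 1].copy()
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        arr = arr[order]
        starts, ends = [], []
        cs, ce = arr[0]
        for s, e in arr[1:]:
            if s <= ce:  # overlapping or bookended -> union
                ce = max(ce, e)
            else:
                starts.append(cs)
                ends.append(ce)
                cs, ce = s, e
        starts.append(cs)
        ends.append(ce)
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return np.array_equal(self.starts, other.starts) and np.array_equal(
            self.ends, other.ends
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet(n={len(self)}, total={self.total_length}, "
            f"label={self.label!r})"
        )

    @property
    def total_length(self) -> int:
        """Sum of interval lengths (bp)."""
        return int(np.sum(self.ends - self.starts))

    def _replace(self, pairs: Iterable[Sequence[int]], label: str | None = None) -> "IntervalSet":
        return IntervalSet(
            pairs,
            genome_id=self.genome_id,
            genome_length=self.genome_length,
            label=self.label if label is None else label,
        )

    # -- set algebra -------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        pairs = list(self) + list(other)
        return self._replace(pairs)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        while i < len(self) and j < len(other):
            s = max(self.starts[i], other.starts[j])
            e = min(self.ends[i], other.ends[j])
            if s < e:
                out.append((s, e))
            if self.ends[i] < other.ends[j]:
                i += 1
            else:
                j += 1
        return self._replace(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Clip away every base covered by ``other``."""
        out = []
        j = 0
        for s, e in self:
            cur = s
            while j < len(other) and other.ends[j] <= cur:
                j += 1
            k = j
            while k < len(other) and other.starts[k] < e:
                if other.starts[k] > cur:
                    out.append((cur, other.starts[k]))
                cur = max(cur, other.ends[k])
                k += 1
            if cur < e:
                out.append((cur, e))
        return self._replace(out)

    def remove_overlapping(self, other: "IntervalSet") -> "IntervalSet":
        """Drop every *whole* interval that overlaps ``other`` by >= 1 bp."""
        keep = [
            (s, e)
            for s, e in self
            if self._point_overlap(other, s, e) == 0
        ]
        return self._replace(keep)

    @staticmethod
    def _point_overlap(other: "IntervalSet", s: int, e: int) -> int:
        ov = np.minimum(other.ends, e) - np.maximum(other.starts, s)
        ov = ov[ov > 0]
        return int(ov.sum())

    def overlap_length(self, other: "IntervalSet") -> int:
        """Total number of base pairs covered by both sets (1-bp resolution)."""
        return self.intersect(other).total_length

    # -- vectorized coverage queries ---------------------------------------

    def coverage_before(self, positions: np.ndarray) -> np.ndarray:
        """Number of covered base pairs in ``[0, p)`` for each position ``p``.

        Enables O(log n) overlap queries for large batches of elements
        (``covered(b) - covered(a)`` is the overlap of ``[a, b)`` with the set).
        """
        positions = np.asarray(positions, dtype=np.int64)
        if len(self) == 0:
            return np.zeros(len(positions), dtype=np.int64)
        lengths = self.ends - self.starts
        cum = np.concatenate([[0], np.cumsum(lengths)])
        idx = np.searchsorted(self.starts, positions, side="right")
        full = cum[idx]
        # partially entered interval: position inside interval idx-1
        prev = idx - 1
        inside = (prev >= 0) & (positions < self.ends[prev.clip(0)])
        correction = np.where(
            inside, self.ends[prev.clip(0)] - positions, 0
        )
        return full - correction

    def batch_overlap(self, q_starts: np.ndarray, q_ends: np.ndarray) -> np.ndarray:
        """Overlap (bp) of each query interval with this set, vectorized."""
        cov = self.coverage_before(np.concatenate([q_starts, q_ends]))
        n = len(q_starts)
        return cov[n:] - cov[:n]

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: is each point inside some interval of the set?"""
        points = np.asarray(points, dtype=np.int64)
        idx = np.searchsorted(self.starts, points, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(points), dtype=bool)
        out[ok] = points[ok] < self.ends[idx[ok]]
        return out

    # -- I/O ----------------------------------------------------------------

    def to_bed(self, path: str | Path, name: str | None = None) -> None:
        chrom = self.genome_id or "genome"
        with open(path, "w") as fh:
            for k, (s, e) in enumerate(self):
                nm = name or self.label or "region"
                fh.write(f"{chrom}\t{s}\t{e}\t{nm}_{k + 1}\n")

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        genome_length: int | None = None,
        label: str = "",
    ) -> "IntervalSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        gid = str(df["chrom"].iloc[0]) if len(df) else ""
        return cls(
            df[["start", "end"]].to_numpy(),
            genome_id=gid,
            genome_length=genome_length,
            label=label,
        )
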