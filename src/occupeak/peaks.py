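"""Peak and unbound-region calling from R-ratio tracks.

A *peak* is a containment-maximal genomic interval of length >= ``min_len``
in which at least ``min_frac`` of positions have R >= ``r_min`` and whose
first and last positions are themselves above threshold.  An *unbound
region* requires R < ``ur_max_r`` at every position in both replicate
experiments over at least ``min_len`` bp, outside any caller-supplied
exclusion set.  Nearby regions separated by a short low-R gap can be merged.

Maximal-interval extraction
---------------------------
Candidate peaks start at the first position of a run of above-threshold
positions and end at the last position of such a run (an interval starting
or ending mid-run is never containment-maximal).  With the prefix score
``S(p) = den * ones(0..p) - num * p`` (``min_frac = num/den`` exactly), an
interval ``[x, y)`` satisfies the fraction constraint iff ``S(y) >= S(x)``,
which reduces maximality to monotone queries over run boundaries and gives
an O(m log m) extraction identical to exhaustive enumeration.  On rare,
precisely balanced tracks two maximal intervals can overlap without their
union qualifying; overlaps are resolved deterministically, longest first and
then leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .intervals import IntervalSet
from .tracks import RatioTrack


@dataclass
class PeakCallParams:
    """Thresholds of the ratio-window caller (defaults are the study's)."""

    r_min: float = 1.5
    min_frac: float = 0.5
    min_len: int = 60
    merge_gap: int = 30
    merge_max_r: float = 1.1
    ur_max_r: float = 1.0
    w: int = 35

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.r_min <= self.ur_max_r:
            raise ValueError("r_min must exceed ur_max_r (peaks above, unbound below)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")

    def frac_ratio(self) -> tuple[int, int]:
        """``min_frac`` as an exact rational (parsed from its decimal form)."""
        f = Fraction(str(float(self.min_frac))).limit_denominator(10**6)
        return f.numerator, f.denominator


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _resolve_overlaps(cands: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep a disjoint subset: longest interval first, then leftmost."""
    chosen: list[tuple[int, int]] = []
    for s, e in sorted(set(cands), key=lambda iv: (iv[0] - iv[1], iv[0])):
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    return sorted(chosen)


def call_peaks(rt: RatioTrack, p: PeakCallParams | None = None) -> IntervalSet:
    """Call bound peaks on one R-ratio track (see module docstring)."""
    p = p or PeakCallParams(w=rt.w)
    above = rt.r >= p.r_min
    runs = _runs(above)
    if not runs:
        return IntervalSet([], genome_id=rt.genome_id, genome_length=len(rt.r),
                           label=f"peaks-{rt.experiment}" if rt.experiment else "peaks")
    num, den = p.frac_ratio()
    # prefix score: S[p] = den * (#above in [0,p)) - num * p
    cum_above = np.concatenate([[0], np.cumsum(above.astype(np.int64))])
    S = den * cum_above - num * np.arange(len(rt.r) + 1, dtype=np.int64)

    run_starts = np.array([r[0] for r in runs], dtype=np.int64)
    run_ends = np.array([r[1] for r in runs], dtype=np.int64)
    S_starts = S[run_starts]
    S_ends = S[run_ends]

    # suffix max of S over run ends -> widest qualifying end for each start
    suf_max = np.maximum.accumulate(S_ends[::-1])[::-1]
    # prefix min of S over run starts strictly before each run
    pre_min = np.concatenate([[np.iinfo(np.int64).max],
                              np.minimum.accumulate(S_starts)[:-1]])

    m = len(runs)
    cands: list[tuple[int, int]] = []
    for a in range(m):
        # largest b with S_ends[b] >= S_starts[a]; suf_max is non-increasing
        lo, hi = a, m - 1
        if suf_max[a] < S_starts[a]:
            continue
        while lo < hi:  # find last index where suf_max >= S_starts[a]
            mid = (lo + hi + 1) // 2
            if suf_max[mid] >= S_starts[a]:
                lo = mid
            else:
                hi = mid - 1
        b = lo
        x, y = int(run_starts[a]), int(run_ends[b])
        if y - x < p.min_len:
            continue
        # dominated if an earlier run start could pair with the same end
        if pre_min[a] <= S[y]:
            continue
        cands.append((x, y))
    chosen = _resolve_overlaps(cands)
    return IntervalSet(chosen, genome_id=rt.genome_id, genome_length=len(rt.r),
                       label=f"peaks-{rt.experiment}" if rt.experiment else "peaks")


def peak_predicate(r: np.ndarray, start: int, end: int, p: PeakCallParams) -> bool:
    """Does ``[start, end)`` satisfy the peak acceptance rule? (self-check)."""
    if end - start < p.min_len:
        return False
    seg = r[start:end]
    if seg[0] < p.r_min or seg[-1] < p.r_min:
        return False
    num, den = p.frac_ratio()
    return int((seg >= p.r_min).sum()) * den >= num * (end - start)


def call_unbound(
    rt1: RatioTrack,
    rt2: RatioTrack,
    exclusions: list[IntervalSet] | None = None,
    p: PeakCallParams | None = None,
) -> IntervalSet:
    """Regions with R < ``ur_max_r`` at every position in *both* experiments.

    Maximal such runs of length >= ``min_len`` are kept, then any interval
    overlapping an exclusion set by >= 1 bp is removed whole (exclusion sets
    are caller-supplied BED, e.g. an external caller's peaks).
    """
    p = p or PeakCallParams(w=rt1.w)
    if len(rt1.r) != len(rt2.r):
        raise ValueError("tracks are on different genomes")
    below = (rt1.r < p.ur_max_r) & (rt2.r < p.ur_max_r)
    regions = [(s, e) for s, e in _runs(below) if e - s >= p.min_len]
    out = IntervalSet(regions, genome_id=rt1.genome_id,
                      genome_length=len(rt1.r), label="UR")
    for excl in exclusions or []:
        out = out.remove_overlapping(excl)
    return out


def merge_regions(
    s: IntervalSet,
    rt: RatioTrack,
    max_gap: int = 30,
    max_intermediate: float = 1.1,
) -> IntervalSet:
    """Combine regions separated by < ``max_gap`` bp when every intermediate
    position has R <= ``max_intermediate``.  Applied iteratively to fixpoint."""
    intervals = list(s)
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        for iv in intervals:
            if merged:
                ps, pe = merged[-1]
                gap = iv[0] - pe
                if 0 <= gap < max_gap and np.all(rt.r[pe : iv[0]] <= max_intermediate):
                    merged[-1] = (ps, iv[1])
                    changed = True
                    continue
            merged.append(tuple(iv))
        intervals = merged
    return IntervalSet(intervals, genome_id=s.genome_id,
                       genome_length=s.genome_length, label=s.label)


def combine_experiments(
    peaks2: IntervalSet,
    unbound1: IntervalSet,
) -> IntervalSet:
    """Combined set (CS): replicate-2 peaks minus any peak overlapping a
    replicate-1 unbound region by >= 1 bp (whole-peak removal, no clipping)."""
    out = peaks2.remove_overlapping(unbound1)
    return IntervalSet(list(out), genome_id=peaks2.genome_id,
                       genome_length=peaks2.genome_length, label="CS")


def peak_report(peaks: IntervalSet, rt: RatioTrack, p: PeakCallParams) -> str:
    """Per-peak TSV: 1-based inclusive coordinates, length, max R, fraction above."""
    lines = ["start_1based\tend_1based\tlength\tmax_r\tfrac_above"]
    for s, e in peaks:
        seg = rt.r[s:e]
        lines.append(
            f"{s + 1}\t{e}\t{e - s}\t{seg.max():.4f}\t{(seg >= p.r_min).mean():.4f}"
        )
    return "\n".join(lines) + "\n"
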