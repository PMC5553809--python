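"""Scaling normalization and window/ratio track construction.

The two anchored profiles (IP and control) are put on a common scale with the
trimmed-mean scaling method used for microarray normalization: the mean of
each profile is computed after discarding a fixed fraction (2% by default) of
the highest- and lowest-intensity positions, and the IP profile is multiplied
by the ratio of the two corrected means.  Read counts are then summed in
running windows (25/35/75 bp; 35 bp default) and the per-position enrichment
ratio R = IP / control is taken, with a pseudocount guarding coverage gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .anchoring import AnchorProfile, write_bedgraph
from .intervals import IntervalSet


@dataclass
class ScalingResult:
    trim: float
    ip_trimmed_mean: float
    ctrl_trimmed_mean: float
    factor: float

    def to_tsv(self) -> str:
        return (
            "trim\tip_trimmed_mean\tctrl_trimmed_mean\tfactor\n"
            f"{self.trim}\t{self.ip_trimmed_mean:.6g}\t"
            f"{self.ctrl_trimmed_mean:.6g}\t{self.factor:.6g}\n"
        )


@dataclass
class CoverageTrack:
    """Per-position running-window read counts."""

    values: np.ndarray
    w: int
    genome_id: str = ""
    circular: bool = True

    def to_bedgraph(self, path: str | Path) -> None:
        write_bedgraph(path, self.genome_id or "genome", self.values)


@dataclass
class RatioTrack:
    """Per-position enrichment ratio R between IP and control window counts."""

    r: np.ndarray
    w: int
    pseudocount: float
    genome_id: str = ""
    experiment: str = ""
    circular: bool = True

    def __len__(self) -> int:
        return len(self.r)

    def to_bedgraph(self, path: str | Path) -> None:
        write_bedgraph(path, self.genome_id or "genome", np.round(self.r, 6))


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean after removing the ``trim`` highest and ``trim`` lowest fractions."""
    return float(stats.trim_mean(np.asarray(values, dtype=float), trim))


def scale_normalize(
    ip: AnchorProfile, ctrl: AnchorProfile, trim: float = 0.02
) -> tuple[np.ndarray, np.ndarray, ScalingResult]:
    """Scale the IP profile onto the control's trimmed-mean intensity.

    Returns ``(scaled_ip, ctrl, result)`` where ``scaled_ip`` is a float
    array ``ip.counts * (ctrl_tm / ip_tm)`` and the control is unchanged.
    The trimmed signals are the per-position anchored counts over all genome
    positions, zeros included.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    if ip.genome_length != ctrl.genome_length:
        raise ValueError("profiles are on different genomes")
    tm_ip = trimmed_mean(ip.counts, trim)
    tm_ctrl = trimmed_mean(ctrl.counts, trim)
    if tm_ip == 0:
        raise ValueError("degenerate IP library: trimmed mean is zero")
    factor = tm_ctrl / tm_ip
    result = ScalingResult(trim=trim, ip_trimmed_mean=tm_ip,
                           ctrl_trimmed_mean=tm_ctrl, factor=factor)
    return ip.counts.astype(float) * factor, ctrl.counts.astype(float), result


def _window_sum(values: np.ndarray, w: int, circular: bool) -> np.ndarray:
    """Sliding sum over the w-length window centered at each position.

    The window at position p covers ``[p - (w-1)//2, p - (w-1)//2 + w)``;
    for odd w this is symmetric.  Circular tracks wrap; linear tracks treat
    out-of-range positions as zero.
    """
    n = len(values)
    left = (w - 1) // 2
    right = w - 1 - left
    if circular:
        head = values[n - left : n] if left else values[:0]
        tail = values[:right]
        ext = np.concatenate([head, values, tail])
    else:
        ext = np.concatenate([np.zeros(left, values.dtype), values,
                              np.zeros(right, values.dtype)])
    cs = np.concatenate([[0], np.cumsum(ext)])
    return cs[w:] - cs[:-w]


def window_counts(
    profile: AnchorProfile | np.ndarray,
    w: int,
    circular: bool = True,
    genome_id: str = "",
) -> CoverageTrack:
    """Running-window read counts (sum over the centered w-bp window)."""
    if isinstance(profile, AnchorProfile):
        values, circular = profile.counts, profile.circular
        genome_id = genome_id or profile.genome_id
    else:
        values = np.asarray(profile)
    if not 1 <= w <= len(values):
        raise ValueError("window must satisfy 1 <= w <= G")
    return CoverageTrack(_window_sum(values, w, circular), w=w,
                         genome_id=genome_id, circular=circular)


def ratio_track(
    ip_track: CoverageTrack,
    ctrl_track: CoverageTrack,
    pseudocount: float = 1.0,
    experiment: str = "",
) -> RatioTrack:
    """R(p) = (ip(p) + pseudocount) / (ctrl(p) + pseudocount)."""
    if len(ip_track.values) != len(ctrl_track.values) or ip_track.w != ctrl_track.w:
        raise ValueError("tracks differ in genome length or window")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = ctrl_track.values + pseudocount
    if pseudocount == 0 and np.any(denom == 0):
        raise ZeroDivisionError("zero control window count with zero pseudocount")
    r = (ip_track.values + pseudocount) / denom
    return RatioTrack(r=r, w=ip_track.w, pseudocount=pseudocount,
                      genome_id=ip_track.genome_id, experiment=experiment,
                      circular=ip_track.circular)


def bin_counts(
    data: AnchorProfile | np.ndarray | IntervalSet,
    bin_size: int = 100_000,
    genome_length: int | None = None,
    percent: bool = False,
) -> np.ndarray:
    """Per-bin totals of a profile, or per-bin covered length of an interval set.

    An interval straddling a bin boundary contributes its length to each bin
    proportionally (length is conserved).  In ``percent`` mode values are
    scaled to sum to 100.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    if isinstance(data, IntervalSet):
        if genome_length is None:
            genome_length = data.genome_length
        if genome_length is None:
            raise ValueError("genome_length required for interval binning")
        n_bins = -(-genome_length // bin_size)
        out = np.zeros(n_bins, dtype=float)
        for s, e in data:
            while s < e:
                b = s // bin_size
                chunk = min(e, (b + 1) * bin_size) - s
                out[b] += chunk
                s += chunk
    else:
        values = data.counts if isinstance(data, AnchorProfile) else np.asarray(data)
        n = len(values)
        n_bins = -(-n // bin_size)
        bins = np.arange(n) // bin_size
        out = np.bincount(bins, weights=values, minlength=n_bins)
    if percent:
        total = out.sum()
        if total == 0:
            raise ValueError("cannot express empty input as percentages")
        out = out / total * 100.0
    return out
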