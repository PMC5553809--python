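"""Observed-vs-expected base-pair overlap statistics (K ratios).

If a set of elements of total length ``L_elements`` and a target interval
set of total length ``L_set`` were placed independently and uniformly on a
genome of ``G`` bp, the expected number of shared base pairs is
``E = (L_elements / G) * L_set``.  The ratio ``K = O / E`` of the observed
to the expected overlap measures co-occurrence beyond chance (K = 1 under
independence).  For repeat catalogs each pair's footprint (arm+spacer+arm)
is a holistic unit; by default footprints are counted with multiplicity
(overlapping footprints contribute independently), matching the additive
totals convention ``L_ij = n_ij * (2i + j)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import IntervalSet
from .repeats import RepeatCatalog

CONVENTIONS = ("multiplicity", "union")


@dataclass
class EnrichmentResult:
    observed: float
    expected: float
    k: float | None
    element_label: str = ""
    target_label: str = ""
    convention: str = "union"

    def to_tsv_row(self) -> str:
        k = f"{self.k:.4f}" if self.k is not None else "NA"
        return (
            f"{self.element_label}\t{self.target_label}\t{self.observed:.6g}\t"
            f"{self.expected:.6g}\t{k}\t{self.convention}"
        )


def expected_overlap(l_elements: float, genome_length: int, l_set: float) -> float:
    """Expected shared base pairs under independent uniform placement."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if l_elements < 0 or l_set < 0:
        raise ValueError("lengths must be non-negative")
    if l_set > genome_length:
        raise ValueError("target set longer than genome")
    if l_elements > genome_length:
        warnings.warn(
            "element total exceeds genome length (multiplicity convention)",
            stacklevel=2,
        )
    return l_elements / genome_length * l_set


def k_ratio(observed: float, expected: float) -> float | None:
    """K = O / E; ``None`` (reported as missing) when E = 0."""
    if expected == 0:
        return None
    return observed / expected


def _split_wrapped(footprints: np.ndarray, genome_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Split [start, end) pairs that run past G into linear pieces.

    Returns flat (starts, ends) arrays; a wrapped footprint contributes two
    rows, so per-element sums must be taken before splitting if needed.
    """
    fp = np.asarray(footprints, dtype=np.int64)
    if fp.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s, e = fp[:, 0] % genome_length, fp[:, 1] - fp[:, 0]
    e = s + e
    plain = e <= genome_length
    starts = [s[plain]]
    ends = [e[plain]]
    if (~plain).any():
        ws, we = s[~plain], e[~plain]
        starts += [ws, np.zeros((~plain).sum(), dtype=np.int64)]
        ends += [np.full((~plain).sum(), genome_length, dtype=np.int64), we - genome_length]
    return np.concatenate(starts), np.concatenate(ends)


def observed_overlap(
    footprints: np.ndarray | list[tuple[int, int]] | IntervalSet,
    target: IntervalSet,
    convention: str = "multiplicity",
    genome_length: int | None = None,
) -> int:
    """Shared base pairs between element footprints and a target set.

    ``multiplicity``: sum over elements of ``|footprint & target|`` (two
    identical footprints count twice).  ``union``: overlap of the merged
    footprint union with the target.  Footprints may extend past G (circular
    wrap); they are split at the origin before intersection.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if isinstance(footprints, IntervalSet):
        fp = np.column_stack([footprints.starts, footprints.ends])
        genome_length = genome_length or footprints.genome_length
    else:
        fp = np.asarray(list(footprints), dtype=np.int64).reshape(-1, 2)
    if genome_length is None:
        genome_length = target.genome_length
    if genome_length is None:
        raise ValueError("genome_length required")
    starts, ends = _split_wrapped(fp, genome_length)
    if convention == "union":
        merged = IntervalSet(
            np.column_stack([starts, ends]), genome_length=genome_length
        )
        return merged.overlap_length(target)
    return int(target.batch_overlap(starts, ends).sum())


def repeat_enrichment(
    cat: RepeatCatalog,
    rtype: str,
    i: int,
    j: int,
    target: IntervalSet,
    convention: str = "multiplicity",
) -> EnrichmentResult:
    """K_ij of one (type, i, j) repeat cell against a target interval set."""
    n, l_elements = cat.totals(rtype, i, j)
    obs = observed_overlap(
        cat.footprints(rtype, i, j), target, convention=convention,
        genome_length=cat.genome_length,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exp = expected_overlap(l_elements, cat.genome_length, target.total_length)
    return EnrichmentResult(
        observed=obs, expected=exp, k=k_ratio(obs, exp),
        element_label=f"{rtype}_i{i}_j{j}", target_label=target.label,
        convention=convention,
    )


def fold_enrichment(a: IntervalSet, b: IntervalSet, genome_length: int) -> EnrichmentResult:
    """Observed vs expected overlap of two interval sets (union convention)."""
    obs = a.overlap_length(b)
    exp = expected_overlap(a.total_length, genome_length, b.total_length)
    return EnrichmentResult(
        observed=obs, expected=exp, k=k_ratio(obs, exp),
        element_label=a.label, target_label=b.label, convention="union",
    )


def compare_k_distributions(
    k_a: list[float], k_b: list[float], test: str = "mannwhitney"
) -> tuple[float, str]:
    """Two-sided comparison of per-(i,j) K values between two sets.

    Rank-based Mann-Whitney U by default (robust for the small per-arm-length
    samples); Welch's t available.  Degenerate all-equal inputs return p = 1
    with a warning.
    """
    if len(k_a) < 3 or len(k_b) < 3:
        raise ValueError("each sample must have length >= 3")
    pooled = np.concatenate([k_a, k_b])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate all-equal samples; p = 1", stacklevel=2)
        return 1.0, test
    if test == "mannwhitney":
        # use the exact U distribution where affordable and tie-free
        no_ties = len(set(pooled.tolist())) == len(pooled)
        method = "exact" if no_ties and max(len(k_a), len(k_b)) <= 25 else "auto"
        res = stats.mannwhitneyu(k_a, k_b, alternative="two-sided", method=method)
    elif test == "welch":
        res = stats.ttest_ind(k_a, k_b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.pvalue), test


def probes_to_intervals(
    probes: list[tuple[int, float]] | np.ndarray,
    min_fold: float = 2.0,
    width: int = 60,
    genome_length: int | None = None,
    label: str = "probes",
) -> IntervalSet:
    """Select >= ``min_fold``-enriched probes and expand each to its
    ``width``-bp window ``[start, start + width)``; overlaps are merged."""
    arr = np.asarray(list(probes), dtype=float).reshape(-1, 2)
    sel = arr[arr[:, 1] >= min_fold, 0].astype(np.int64)
    pairs = np.column_stack([sel, sel + width])
    return IntervalSet(pairs, genome_length=genome_length, label=label)


def points_to_intervals(
    points: list[int] | np.ndarray,
    width: int,
    genome_length: int | None = None,
    label: str = "points",
) -> IntervalSet:
    """Expand point coordinates (e.g. peak maxima) to centered ``width``-bp
    intervals ``[p - width//2, p - width//2 + width)``; overlaps are merged."""
    if width < 1:
        raise ValueError("width must be >= 1")
    pts = np.asarray(points, dtype=np.int64)
    starts = pts - width // 2
    return IntervalSet(
        np.column_stack([starts, starts + width]),
        genome_length=genome_length, label=label,
    )


def permutation_expected_overlap(
    element_lengths: np.ndarray,
    target: IntervalSet,
    genome_length: int,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo check of the closed-form expectation.

    Elements are repositioned uniformly on the circular genome ``n_draws``
    times; returns the mean observed overlap and its standard error.
    """
    rng = rng or np.random.default_rng()
    lengths = np.asarray(element_lengths, dtype=np.int64)
    totals = np.empty(n_draws)
    for d in range(n_draws):
        starts = rng.integers(0, genome_length, size=len(lengths))
        fp = np.column_stack([starts, starts + lengths])
        totals[d] = observed_overlap(
            fp, target, convention="multiplicity", genome_length=genome_length
        )
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n_draws))
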