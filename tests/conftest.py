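"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (string slicing, position
sets, sort-and-slice) so they share no code path with the vectorized
implementations they check.
"""

from fractions import Fraction

import numpy as np
import pytest

from occupeak.genome import Genome, reverse_complement

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_genome(rng, length, circular=True, gc=0.5):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list(BASES), size=length, p=probs))
    return Genome(id="toy", sequence=seq, circular=circular)


# ---------------------------------------------------------------------------
# oracles


def oracle_repeat_scan(seq, circular, rtype, i_range, j_range):
    """Quadruple-loop repeat enumeration on a plain string."""
    g = len(seq)
    ext = seq + seq
    out = {}
    for i in i_range:
        for j in j_range:
            span = 2 * i + j
            hits = []
            if span <= g:
                stop = g if circular else g - span + 1
                for p in range(stop):
                    arm1 = ext[p : p + i]
                    arm2 = ext[p + i + j : p + span]
                    if rtype == "direct":
                        if arm1 == arm2:
                            hits.append(p)
                    elif arm2 == reverse_complement(arm1):
                        hits.append(p)
            out[(rtype, i, j)] = hits
    return out


def oracle_peak_predicate(r, s, e, params):
    if e - s < params.min_len:
        return False
    if r[s] < params.r_min or r[e - 1] < params.r_min:
        return False
    fr = Fraction(str(float(params.min_frac)))
    ones = sum(1 for p in range(s, e) if r[p] >= params.r_min)
    return ones * fr.denominator >= fr.numerator * (e - s)


def oracle_call_peaks(r, params):
    """Exhaustive enumeration: all qualifying intervals, containment-maximal,
    then the documented longest-first/leftmost disjoint resolution."""
    fr = Fraction(str(float(params.min_frac)))
    n = len(r)
    above = [x >= params.r_min for x in r]
    cands = []
    for s in range(n):
        if not above[s]:
            continue
        ones = 0
        best = None
        for e in range(s + 1, n + 1):
            if above[e - 1]:
                ones += 1
                if (
                    e - s >= params.min_len
                    and ones * fr.denominator >= fr.numerator * (e - s)
                ):
                    best = e
        if best is not None:
            cands.append((s, best))
    maximal = [
        c
        for c in cands
        if not any(o != c and o[0] <= c[0] and o[1] >= c[1] for o in cands)
    ]
    chosen = []
    for s, e in sorted(set(maximal), key=lambda iv: (iv[0] - iv[1], iv[0])):
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    return sorted(chosen)


def oracle_call_unbound(r1, r2, min_len, ur_max_r):
    """Position-wise evaluation of the both-tracks-below rule."""
    n = len(r1)
    out = []
    s = None
    for p in range(n + 1):
        ok = p < n and r1[p] < ur_max_r and r2[p] < ur_max_r
        if ok and s is None:
            s = p
        elif not ok and s is not None:
            if p - s >= min_len:
                out.append((s, p))
            s = None
    return out


def oracle_overlap_bp(intervals_a, intervals_b):
    """Shared base pairs via explicit position sets."""
    pos_a = set()
    for s, e in intervals_a:
        pos_a.update(range(s, e))
    pos_b = set()
    for s, e in intervals_b:
        pos_b.update(range(s, e))
    return len(pos_a & pos_b)


def oracle_trimmed_mean(values, trim):
    """Sort-and-slice trimmed mean."""
    vals = sorted(values)
    k = int(trim * len(vals))
    sel = vals[k : len(vals) - k]
    return sum(sel) / len(sel)


def oracle_anchor(read, seq, circular):
    """Slide the read and its reverse complement along the genome."""
    g = len(seq)
    L = len(read)
    ext = seq + seq[: L - 1] if circular else seq
    rc = reverse_complement(read)
    hits = set()
    for p in range(g if circular else g - L + 1):
        window = ext[p : p + L]
        if window == read or window == rc:
            hits.add(p)
    return sorted(hits)
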