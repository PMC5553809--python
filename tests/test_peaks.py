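"""Peak calling, unbound-region calling, merging and replicate combination."""

import numpy as np
import pytest

from occupeak.intervals import IntervalSet
from occupeak.peaks import (PeakCallParams, call_peaks, call_unbound,
                            combine_experiments, merge_regions, peak_predicate)
from occupeak.tracks import RatioTrack

from conftest import oracle_call_peaks, oracle_call_unbound


def track(values, w=35):
    return RatioTrack(np.asarray(values, dtype=float), w=w, pseudocount=1.0)


def random_track(rng, n=600):
    """Blocky R tracks with values straddling every threshold of interest."""
    vals = []
    while len(vals) < n:
        level = rng.choice([0.7, 0.95, 1.0, 1.05, 1.3, 1.5, 1.7, 2.5])
        vals += [level] * int(rng.integers(3, 40))
    return track(vals[:n])


class TestCallPeaks:
    def test_flat_unity_track_empty(self):
        assert len(call_peaks(track([1.0] * 500))) == 0

    def test_exact_60bp_block(self):
        r = np.full(400, 1.0)
        r[100:160] = 1.6
        assert list(call_peaks(track(r))) == [(100, 160)]

    def test_59bp_block_rejected(self):
        r = np.full(400, 1.0)
        r[100:159] = 1.6
        assert len(call_peaks(track(r))) == 0

    def test_half_fraction_boundary_inclusive(self):
        """29/60 positions above threshold fails; 30/60 qualifies."""
        p = PeakCallParams()
        base30 = [1.6] * 15 + [1.0] * 30 + [1.6] * 15  # 30 of 60 above
        base29 = [1.6] * 15 + [1.0] * 31 + [1.6] * 14  # 29 of 60 above
        assert peak_predicate(np.array(base30), 0, 60, p)
        assert not peak_predicate(np.array(base29), 0, 60, p)
        r = np.full(200, 1.0)
        r[70:130] = base30
        assert list(call_peaks(track(r), p)) == [(70, 130)]
        r[70:130] = 1.0
        r[70:129] = base29[:59]  # same shape, one above-position short
        assert len(call_peaks(track(r), p)) == 0

    def test_emitted_peaks_self_verify(self, rng):
        p = PeakCallParams()
        for _ in range(20):
            rt = random_track(rng)
            for s, e in call_peaks(rt, p):
                assert peak_predicate(rt.r, s, e, p)

    def test_matches_enumeration_oracle(self, rng):
        p = PeakCallParams()
        for _ in range(15):
            rt = random_track(rng, n=400)
            assert list(call_peaks(rt, p)) == oracle_call_peaks(rt.r, p)

    def test_raising_threshold_never_grows_peaks(self, rng):
        for _ in range(5):
            rt = random_track(rng)
            lo = call_peaks(rt, PeakCallParams(r_min=1.4)).total_length
            hi = call_peaks(rt, PeakCallParams(r_min=1.6)).total_length
            assert hi <= lo

    def test_disjoint_from_unbound(self, rng):
        p = PeakCallParams()
        rt = random_track(rng)
        peaks = call_peaks(rt, p)
        ur = call_unbound(rt, rt, None, p)
        assert peaks.overlap_length(ur) == 0


class TestCallUnbound:
    def test_everywhere_low_spans_genome(self):
        rt = track([0.8] * 300)
        assert list(call_unbound(rt, rt)) == [(0, 300)]

    def test_single_boundary_position_splits(self):
        r1 = np.full(300, 0.8)
        r1[100] = 1.0  # strict < 1.0 required
        r2 = np.full(300, 0.8)
        got = call_unbound(track(r1), track(r2))
        assert list(got) == [(0, 100), (101, 300)]
        # an 80-bp region split by one such position leaves only short scraps
        r3 = np.full(300, 1.4)
        r3[100:180] = 0.8
        r3[140] = 1.0
        assert len(call_unbound(track(r3), track(r3))) == 0

    def test_requires_both_experiments_low(self):
        r1 = np.full(200, 0.5)
        r2 = np.full(200, 0.5)
        r2[80:90] = 1.2
        got = call_unbound(track(r1), track(r2))
        assert list(got) == [(0, 80), (90, 200)]

    def test_exclusion_removes_whole_region(self):
        rt = track([0.8] * 400)
        excl = IntervalSet([(150, 151)])
        assert len(call_unbound(rt, rt, [excl])) == 0

    def test_matches_positionwise_oracle(self, rng):
        p = PeakCallParams()
        for _ in range(10):
            a, b = random_track(rng, 400), random_track(rng, 400)
            got = list(call_unbound(a, b, None, p))
            assert got == oracle_call_unbound(a.r, b.r, p.min_len, p.ur_max_r)


class TestMergeRegions:
    def make(self, gap, gap_value):
        r = np.full(300, 0.8)
        r[50:100] = 1.8
        r[100 + gap : 160 + gap] = 1.8
        r[100 : 100 + gap] = gap_value
        return IntervalSet([(50, 100), (100 + gap, 160 + gap)]), track(r)

    def test_29bp_gap_low_intermediate_merges(self):
        s, rt = self.make(29, 1.05)
        assert list(merge_regions(s, rt)) == [(50, 189)]

    def test_30bp_gap_not_merged(self):
        s, rt = self.make(30, 1.05)
        assert len(merge_regions(s, rt)) == 2

    def test_intermediate_above_1p1_blocks_merge(self):
        s, rt = self.make(29, 1.2)
        assert len(merge_regions(s, rt)) == 2
        s, rt = self.make(29, 1.1)  # "did not exceed 1.1" is inclusive
        assert len(merge_regions(s, rt)) == 1

    def test_chain_merges_to_fixpoint(self):
        r = np.full(400, 1.05)
        s = IntervalSet([(0, 70), (80, 150), (160, 230), (240, 310)])
        assert list(merge_regions(s, track(r))) == [(0, 310)]


class TestCombineExperiments:
    def test_overlap_rules(self):
        peaks2 = IntervalSet([(0, 100), (200, 300), (400, 500)], label="peaks")
        unbound1 = IntervalSet([(299, 310), (600, 700)])
        cs = combine_experiments(peaks2, unbound1)
        assert list(cs) == [(0, 100), (400, 500)]  # 1-bp overlap removes whole peak
        assert cs.label == "CS"

    def test_empty_unbound_identity(self):
        peaks2 = IntervalSet([(10, 80)])
        assert list(combine_experiments(peaks2, IntervalSet([]))) == [(10, 80)]


def test_params_validation():
    with pytest.raises(ValueError, match="r_min"):
        PeakCallParams(r_min=0.9, ur_max_r=1.0)
    with pytest.raises(ValueError):
        PeakCallParams(min_frac=0.0)
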