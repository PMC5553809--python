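"""Scaling normalization, window counts, ratio tracks and binning."""

import numpy as np
import pytest

from occupeak.anchoring import AnchorProfile
from occupeak.intervals import IntervalSet
from occupeak.tracks import (bin_counts, ratio_track, scale_normalize,
                             window_counts)

from conftest import oracle_trimmed_mean


def profile(counts, **kw):
    return AnchorProfile("toy", np.asarray(counts), **kw)


class TestScaleNormalize:
    def test_identical_profiles_factor_one(self, rng):
        c = rng.poisson(8, size=1000)
        ip, ctrl, res = scale_normalize(profile(c), profile(c.copy()))
        assert res.factor == pytest.approx(1.0)
        np.testing.assert_allclose(ip, c)

    def test_constant_profiles(self):
        ip, ctrl, res = scale_normalize(profile([20] * 500), profile([10] * 500))
        assert res.factor == pytest.approx(0.5)
        assert (ip == 10).all() and (ctrl == 10).all()

    def test_factor_matches_sort_and_slice_oracle(self, rng):
        ctrl = rng.poisson(5, size=1000)
        ip = rng.poisson(9, size=1000)
        spikes = rng.choice(1000, size=20, replace=False)
        ip[spikes] += rng.integers(50, 500, size=20)
        _, _, res = scale_normalize(profile(ip), profile(ctrl), trim=0.02)
        expect = oracle_trimmed_mean(ctrl, 0.02) / oracle_trimmed_mean(ip, 0.02)
        assert res.factor == pytest.approx(expect, rel=1e-12)
        assert res.ip_trimmed_mean == pytest.approx(oracle_trimmed_mean(ip, 0.02))

    def test_trimmed_means_equal_after_scaling(self, rng):
        ctrl = rng.poisson(5, size=2000)
        ip = rng.poisson(12, size=2000)
        scaled_ip, _, res = scale_normalize(profile(ip), profile(ctrl))
        assert oracle_trimmed_mean(scaled_ip, 0.02) == pytest.approx(
            oracle_trimmed_mean(ctrl, 0.02), rel=1e-9
        )

    def test_scale_equivariance(self, rng):
        """Multiplying the IP library by a constant leaves scaled IP unchanged."""
        ctrl = rng.poisson(6, size=800)
        ip = rng.poisson(6, size=800)
        a, _, _ = scale_normalize(profile(ip), profile(ctrl))
        b, _, _ = scale_normalize(profile(ip * 7), profile(ctrl))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_ip_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_normalize(profile([0] * 100), profile([5] * 100))


class TestWindowCounts:
    def test_constant_profile(self):
        t = window_counts(profile([3] * 200), 35)
        assert (t.values == 105).all()

    def test_single_count_spreads_over_w_positions(self):
        c = np.zeros(200, dtype=int)
        c[100] = 1
        t = window_counts(profile(c), 35)
        covered = np.flatnonzero(t.values == 1)
        assert len(covered) == 35
        assert covered.min() == 100 - 17 and covered.max() == 100 + 17
        assert t.values.sum() == 35

    def test_w1_is_identity(self, rng):
        c = rng.poisson(3, size=150)
        np.testing.assert_array_equal(window_counts(profile(c), 1).values, c)

    def test_mass_conservation_circular(self, rng):
        c = rng.poisson(2, size=313)
        for w in (25, 35, 75):
            assert window_counts(profile(c), w).values.sum() == w * c.sum()

    def test_circular_wrap(self):
        c = np.zeros(100, dtype=int)
        c[0] = 1
        t = window_counts(profile(c), 25)
        assert t.values[88] == 1 and t.values[12] == 1 and t.values[13] == 0


class TestRatioTrack:
    def test_equal_tracks_give_unity(self, rng):
        c = rng.poisson(10, size=300).astype(float)
        rt = ratio_track(window_counts(c, 35), window_counts(c.copy(), 35), 1.0)
        np.testing.assert_allclose(rt.r, 1.0)

    def test_peak_threshold_arithmetic(self):
        ip = window_counts(np.array([30.0] * 100), 1)
        ctrl = window_counts(np.array([20.0] * 100), 1)
        rt = ratio_track(ip, ctrl, pseudocount=0.0)
        assert rt.r[0] == pytest.approx(1.5)

    def test_elementwise_oracle(self, rng):
        a = rng.poisson(5, size=200).astype(float)
        b = rng.poisson(5, size=200).astype(float)
        rt = ratio_track(window_counts(a, 1), window_counts(b, 1), 0.5)
        for p in (0, 17, 199):
            assert rt.r[p] == pytest.approx((a[p] + 0.5) / (b[p] + 0.5))

    def test_zero_denominator_guard(self):
        z = window_counts(np.zeros(10), 1)
        with pytest.raises(ZeroDivisionError):
            ratio_track(z, z, pseudocount=0.0)

    def test_invariant_to_joint_rescaling(self, rng):
        a = rng.poisson(5, size=100).astype(float) + 1
        b = rng.poisson(5, size=100).astype(float) + 1
        r1 = ratio_track(window_counts(a, 1), window_counts(b, 1), 0.0)
        r2 = ratio_track(window_counts(a * 3, 1), window_counts(b * 3, 1), 0.0)
        np.testing.assert_allclose(r1.r, r2.r)


class TestBinCounts:
    def test_profile_bins_match_oracle_accumulation(self, rng):
        c = rng.poisson(4, size=950)
        out = bin_counts(c, bin_size=100)
        expect = [c[k * 100 : (k + 1) * 100].sum() for k in range(10)]
        np.testing.assert_allclose(out, expect)

    def test_intervals_single_bin_100_percent(self):
        s = IntervalSet([(10, 60)], genome_length=1000)
        out = bin_counts(s, bin_size=100, percent=True)
        assert out[0] == pytest.approx(100.0) and out[1:].sum() == 0

    def test_straddling_interval_split_proportionally(self):
        s = IntervalSet([(80, 130)], genome_length=300)
        out = bin_counts(s, bin_size=100)
        assert out[0] == 20 and out[1] == 30
        assert out.sum() == s.total_length  # length conserved

    def test_empty_percent_mode_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bin_counts(IntervalSet([], genome_length=100), 10, percent=True)
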