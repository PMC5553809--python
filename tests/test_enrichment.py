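"""Observed-vs-expected overlap statistics and interval conversions."""

import numpy as np
import pytest

from occupeak.enrichment import (compare_k_distributions, expected_overlap,
                                 fold_enrichment, k_ratio, observed_overlap,
                                 permutation_expected_overlap,
                                 points_to_intervals, probes_to_intervals,
                                 repeat_enrichment)
from occupeak.intervals import IntervalSet
from occupeak.repeats import scan_repeats

from conftest import oracle_overlap_bp, random_genome


class TestExpectedOverlap:
    def test_published_worked_example(self):
        """38909 bp of elements vs a 109330 bp target on a 4641652 bp genome."""
        e = expected_overlap(38909, 4_641_652, 109_330)
        assert round(e) == 916

    def test_zero_elements(self):
        assert expected_overlap(0, 1000, 300) == 0

    def test_full_genome_target(self):
        assert expected_overlap(123, 1000, 1000) == pytest.approx(123)

    def test_multiplicity_excess_warns(self):
        with pytest.warns(UserWarning, match="multiplicity"):
            expected_overlap(1500, 1000, 200)

    def test_invalid_genome_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap(10, 0, 10)


class TestKRatio:
    def test_published_worked_example(self):
        e = expected_overlap(38909, 4_641_652, 109_330)
        assert round(k_ratio(1134, e), 2) == 1.24

    def test_identity_and_missing(self):
        assert k_ratio(5.0, 5.0) == 1.0
        assert k_ratio(5.0, 0.0) is None


class TestObservedOverlap:
    target = IntervalSet([(100, 200), (500, 600)], genome_length=1000)

    def test_footprint_inside_target(self):
        assert observed_overlap([(120, 133)], self.target) == 13

    def test_disjoint_footprint(self):
        assert observed_overlap([(300, 313)], self.target) == 0

    def test_multiplicity_vs_union(self):
        fp = [(120, 133), (120, 133)]
        assert observed_overlap(fp, self.target, "multiplicity") == 26
        assert observed_overlap(fp, self.target, "union") == 13

    def test_wrapped_footprint_split_at_origin(self):
        target = IntervalSet([(0, 10), (990, 1000)], genome_length=1000)
        assert observed_overlap([(995, 1008)], target, genome_length=1000) == 13

    def test_matches_position_set_oracle(self, rng):
        for _ in range(10):
            fp = [(int(s), int(s + rng.integers(5, 30)))
                  for s in rng.integers(0, 900, size=15)]
            tgt_raw = [(int(s), int(s + rng.integers(10, 80)))
                       for s in rng.integers(0, 900, size=6)]
            tgt = IntervalSet(tgt_raw, genome_length=1000)
            got = observed_overlap(fp, tgt, "union", genome_length=1000)
            assert got == oracle_overlap_bp(fp, list(tgt))
            got_m = observed_overlap(fp, tgt, "multiplicity", genome_length=1000)
            assert got_m == sum(oracle_overlap_bp([f], list(tgt)) for f in fp)


class TestFoldEnrichment:
    def test_self_overlap_is_inverse_fraction(self):
        a = IntervalSet([(0, 250)], genome_length=1000, label="a")
        res = fold_enrichment(a, a, 1000)
        assert res.k == pytest.approx(4.0)  # 1/f with f = 0.25

    def test_disjoint_sets_zero(self):
        a = IntervalSet([(0, 100)], label="a")
        b = IntervalSet([(200, 300)], label="b")
        assert fold_enrichment(a, b, 1000).k == 0

    def test_symmetry(self, rng):
        a = IntervalSet([(10, 60), (200, 260)], label="a")
        b = IntervalSet([(50, 90), (500, 700)], label="b")
        ra, rb = fold_enrichment(a, b, 1000), fold_enrichment(b, a, 1000)
        assert ra.observed == rb.observed and ra.k == pytest.approx(rb.k)

    def test_k_invariant_under_joint_shift(self):
        a = IntervalSet([(100, 160)], label="a")
        b = IntervalSet([(130, 200)], label="b")
        a2 = IntervalSet([(400, 460)])
        b2 = IntervalSet([(430, 500)])
        assert fold_enrichment(a, b, 1000).k == pytest.approx(
            fold_enrichment(a2, b2, 1000).k
        )


class TestRepeatEnrichment:
    def test_k_of_planted_repeat_rich_target(self, rng):
        g = random_genome(rng, 5000)
        cat = scan_repeats(g, "inverted", [5], [3])
        fp = cat.footprints("inverted", 5, 3)
        fp = fp[fp[:, 1] <= 5000][:5]  # non-wrapping footprints
        assert len(fp) > 0
        # a target made of repeat footprints is maximally enriched
        target = IntervalSet(fp, genome_length=5000, label="tgt")
        res = repeat_enrichment(cat, "inverted", 5, 3, target)
        assert res.observed >= target.total_length
        assert res.k > 1


class TestCompareK:
    def test_identical_lists_p1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, _ = compare_k_distributions([1.0] * 5, [1.0] * 5)
        assert p == 1.0

    def test_clear_shift_significant(self):
        base = [1.0, 1.1, 0.9, 1.05, 0.95, 1.2, 0.8, 1.02, 1.15]  # tie-free
        shifted = [x + 10 for x in base]
        p, test = compare_k_distributions(shifted, base)
        assert p < 0.01 and test == "mannwhitney"
        # exact two-sided U p-value for complete separation, n = m = 9
        from math import comb
        assert p == pytest.approx(2 / comb(18, 9), rel=1e-6)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_k_distributions([1.0, 2.0], [1.0, 2.0, 3.0])


class TestConversions:
    def test_probe_fold_boundary(self):
        probes = [(0, 2.0), (100, 1.99), (200, 5.0)]
        s = probes_to_intervals(probes, min_fold=2.0, width=60)
        assert list(s) == [(0, 60), (200, 260)]

    def test_adjacent_probes_merge(self):
        s = probes_to_intervals([(0, 3.0), (30, 3.0)], width=60)
        assert list(s) == [(0, 90)]

    def test_point_expansion_centered(self):
        s = points_to_intervals([100], width=36)
        assert list(s) == [(82, 118)]

    def test_close_points_merge_and_width1(self):
        assert list(points_to_intervals([100, 110], width=36)) == [(82, 128)]
        assert list(points_to_intervals([5, 9], width=1)) == [(5, 6), (9, 10)]


class TestPermutationNull:
    def test_monte_carlo_mean_matches_closed_form(self):
        rng = np.random.default_rng(5)
        target = IntervalSet(
            [(s, s + 40) for s in range(0, 2000, 200)], genome_length=2000
        )
        lengths = np.full(30, 13)
        mean, se = permutation_expected_overlap(lengths, target, 2000,
                                                n_draws=600, rng=rng)
        expect = expected_overlap(30 * 13, 2000, target.total_length)
        assert abs(mean - expect) <= 3 * se
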