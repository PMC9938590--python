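"""Interval overlap counting and permutation enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import proxitome as px
from proxitome.overlap import permutation_enrichment_test

from oracles import overlap_bruteforce


def _random_peaks(rng, n, sizes, max_len=500, label=""):
    chroms = rng.choice(list(sizes.sizes), size=n)
    lens = rng.integers(1, max_len, size=n)
    limits = np.array([sizes[c] for c in chroms])
    lens = np.minimum(lens, limits)
    starts = rng.integers(0, limits - lens + 1)
    return px.PeakSet(chroms.astype(object), starts, starts + lens, label=label)


class TestCountOverlapping:
    def test_identity_counts_all(self, toy_sizes, rng):
        peaks = _random_peaks(rng, 5, toy_sizes)
        assert px.count_overlapping(peaks, peaks) == 5

    def test_half_open_adjacency_is_not_overlap(self):
        q = px.PeakSet.from_intervals([("chr1", 0, 10)])
        t = px.PeakSet.from_intervals([("chr1", 10, 20)])
        assert px.count_overlapping(q, t) == 0

    def test_single_shared_base_counts(self):
        q = px.PeakSet.from_intervals([("chr1", 0, 10)])
        t = px.PeakSet.from_intervals([("chr1", 9, 20)])
        assert px.count_overlapping(q, t) == 1

    def test_each_query_counted_once_despite_many_targets(self):
        q = px.PeakSet.from_intervals([("chr1", 0, 100)])
        t = px.PeakSet.from_intervals([("chr1", 0, 10), ("chr1", 20, 30),
                                       ("chr1", 50, 60)])
        assert px.count_overlapping(q, t) == 1

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_all_pairs_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        sizes = px.ChromSizes({"chr1": 2000, "chr2": 1500})
        q = _random_peaks(rng, int(rng.integers(1, 101)), sizes, max_len=300)
        t = _random_peaks(rng, int(rng.integers(1, 101)), sizes, max_len=300)
        assert px.count_overlapping(q, t) == overlap_bruteforce(q, t)


class TestPermutePeaks:
    def test_lengths_and_chromosomes_preserved(self, toy_sizes, rng):
        peaks = _random_peaks(rng, 50, toy_sizes)
        perm = px.permute_peaks(peaks, toy_sizes, seed=3)
        assert sorted(perm.lengths) == sorted(peaks.lengths)
        assert list(perm.chroms) == list(peaks.chroms)
        perm.validate_against(toy_sizes)

    def test_full_length_interval_start_forced_to_zero(self):
        sizes = px.ChromSizes({"chr1": 100})
        peaks = px.PeakSet.from_intervals([("chr1", 0, 100)])
        perm = px.permute_peaks(peaks, sizes, seed=1)
        assert perm.starts[0] == 0

    def test_oversized_interval_errors(self):
        sizes = px.ChromSizes({"chr1": 100})
        peaks = px.PeakSet(np.array(["chr1"], dtype=object),
                           np.array([0]), np.array([100]))
        with pytest.raises(px.ValidationError):
            px.permute_peaks(peaks, px.ChromSizes({"chr1": 50}), seed=1)

    def test_start_distribution_uniform(self):
        sizes = px.ChromSizes({"chr1": 1000})
        peaks = px.PeakSet.from_intervals([("chr1", 0, 1)])
        rng = np.random.default_rng(11)
        starts = np.array([px.permute_peaks(peaks, sizes, rng).starts[0]
                           for _ in range(10_000)])
        observed, _ = np.histogram(starts, bins=20, range=(0, 1000))
        expected = 10_000 / 20
        chi2 = ((observed - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.99, df=19)


class TestPermutationTest:
    def test_minimum_empirical_p_is_one_over_nperm_plus_one(self, toy_sizes):
        query, target = px.generate_peak_sets(
            toy_sizes, 40, 40, "coincident", offset_sd=0.0, seed=5)
        res = permutation_enrichment_test(query, target, toy_sizes,
                                          n_permutations=100, seed=5)
        assert res.p_empirical >= 1 / 101
        assert res.p_empirical == pytest.approx(1 / 101)
        assert res.fold_enrichment > 2

    def test_saturated_target_gives_fold_one_p_one(self, toy_sizes):
        query, _ = px.generate_peak_sets(toy_sizes, 10, 10, "independent",
                                         seed=2)
        whole = px.PeakSet.from_intervals(
            [(c, 0, L) for c, L in toy_sizes.items()], label="whole")
        res = permutation_enrichment_test(query, whole, toy_sizes,
                                          n_permutations=50, seed=1)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_empirical == 1.0

    def test_seed_reproduces_permuted_counts(self, toy_sizes):
        query, target = px.generate_peak_sets(toy_sizes, 20, 20,
                                              "independent", seed=4)
        r1 = permutation_enrichment_test(query, target, toy_sizes, 30, seed=9)
        r2 = permutation_enrichment_test(query, target, toy_sizes, 30, seed=9)
        np.testing.assert_array_equal(r1.permuted_counts, r2.permuted_counts)

    def test_null_pairs_fold_near_one(self):
        sizes = px.ChromSizes({"chr1": 200_000, "chr2": 200_000})
        folds = []
        for seed in range(30):
            query, target = px.generate_peak_sets(sizes, 50, 50,
                                                  "independent", seed=seed)
            res = permutation_enrichment_test(query, target, sizes,
                                              n_permutations=60, seed=seed)
            folds.append(res.fold_enrichment)
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 1.0) < 3 * se + 0.05

    def test_empty_sets_error(self, toy_sizes):
        empty = px.PeakSet(np.array([], dtype=object),
                           np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64))
        query, target = px.generate_peak_sets(toy_sizes, 5, 5,
                                              "independent", seed=0)
        with pytest.raises(px.ValidationError):
            permutation_enrichment_test(empty, target, toy_sizes)
        with pytest.raises(px.ValidationError):
            permutation_enrichment_test(query, empty, toy_sizes)


class TestBatchOverlap:
    def test_planted_targets_flagged_independent_not(self, toy_sizes):
        query, t_coin = px.generate_peak_sets(toy_sizes, 40, 40, "coincident",
                                              offset_sd=0.0, seed=21)
        t_coin.label = "planted"
        _, t_ind = px.generate_peak_sets(toy_sizes, 40, 40, "independent",
                                         seed=22)
        t_ind.label = "independent"
        table, summary = px.batch_overlap(query, [t_coin, t_ind], toy_sizes,
                                          n_permutations=100, seed=1)
        assert bool(table.loc["planted", "significant"])
        assert summary["targets_tested"] == 2

    def test_duplicate_labels_error(self, toy_sizes):
        q, t = px.generate_peak_sets(toy_sizes, 5, 5, "independent", seed=0)
        t2 = px.PeakSet(t.chroms, t.starts, t.ends, label=t.label)
        with pytest.raises(px.ValidationError, match="duplicate"):
            px.batch_overlap(q, [t, t2], toy_sizes)

    def test_empty_target_list_errors(self, toy_sizes):
        q, _ = px.generate_peak_sets(toy_sizes, 5, 5, "independent", seed=0)
        with pytest.raises(px.ValidationError):
            px.batch_overlap(q, [], toy_sizes)

    def test_per_target_failure_is_flagged_row(self, toy_sizes):
        q, t = px.generate_peak_sets(toy_sizes, 5, 5, "independent", seed=0)
        empty = px.PeakSet(np.array([], dtype=object),
                           np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64), label="broken")
        table, _ = px.batch_overlap(q, [t, empty], toy_sizes,
                                    n_permutations=20, seed=2)
        assert table.loc["broken", "error"] != ""
        assert table.loc["target", "error"] == ""
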