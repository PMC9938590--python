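"""Generator contracts: determinism, planted structure, MNAR behavior."""

import numpy as np
import pandas as pd
import pytest

import proxitome as px
from proxitome.synthetic import (
    LABEL_SHARED, generate_annotation_tables, generate_peak_sets,
    generate_signal_track,
)


class TestAbundanceStudy:
    def test_same_seed_is_byte_identical_different_seed_differs(self, small_config):
        m1, _ = px.generate_abundance_study(small_config)
        m2, _ = px.generate_abundance_study(small_config)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        other = px.SyntheticStudyConfig(**{**small_config.__dict__, "seed": 43})
        m3, _ = px.generate_abundance_study(other)
        assert not m1.values.equals(m3.values)

    def test_design_layout(self, small_study):
        _, matrix, _ = small_study
        meta = matrix.metadata
        # experiment 1 has no dcas9 samples; experiment 2 has all five
        assert set(meta.loc[meta.experiment == "exp1", "condition"]) == {
            "control", "turboid", "nt_kdm5", "ct_kdm5"}
        assert set(meta.loc[meta.experiment == "exp2", "condition"]) == {
            "control", "turboid", "dcas9", "nt_kdm5", "ct_kdm5"}
        assert (meta.experiment == "exp1").sum() == 4 * 4
        assert (meta.experiment == "exp2").sum() == 5 * 3

    def test_planted_interactors_are_nuclear_and_exist(self, small_study):
        _, matrix, truth = small_study
        for pid in truth.planted_interactors:
            assert pid in matrix.values.index
            assert pid in truth.nuclear
        # labels are mutually exclusive by construction (one dict)
        labels = set(truth.labels.values())
        assert labels <= {"shared", "nt_only", "ct_only",
                          "background_biased", "null"}

    def test_mnar_missing_rate_decreases_with_intensity(self):
        cfg = px.SyntheticStudyConfig(n_proteins=2000, seed=3,
                                      missingness_midpoint_log2=18.0,
                                      missingness_slope=1.0)
        matrix, _ = px.generate_abundance_study(cfg)
        log2 = np.log2(matrix.values.to_numpy())
        present_mean = np.nanmean(log2, axis=1)
        miss_rate = matrix.values.isna().mean(axis=1).to_numpy()
        bins = np.quantile(present_mean[~np.isnan(present_mean)],
                           [0, .25, .5, .75, 1.0])
        rates = [miss_rate[(present_mean >= lo) & (present_mean < hi)].mean()
                 for lo, hi in zip(bins[:-1], bins[1:])]
        assert all(a >= b - 1e-12 for a, b in zip(rates[:-1], rates[1:]))

    def test_degenerate_slope_gives_constant_half_missingness(self):
        cfg = px.SyntheticStudyConfig(n_proteins=2000, seed=5,
                                      missingness_slope=0.0)
        matrix, _ = px.generate_abundance_study(cfg)
        frac = matrix.values.isna().to_numpy().mean()
        # logistic(0 * anything) = 0.5 for every cell
        assert abs(frac - 0.5) < 0.01

    def test_planted_effect_recovered_at_many_replicates(self):
        # negligible dropout so the observed-cell contrast is unconfounded
        cfg = px.SyntheticStudyConfig(
            n_proteins=50, n_true_shared=10, n_true_nt_only=0,
            n_true_ct_only=0, n_background_biased=0,
            replicates_exp1=100, missingness_midpoint_log2=0.0, seed=11)
        matrix, truth = px.generate_abundance_study(cfg)
        bait = matrix.samples_for("nt_kdm5", "exp1")
        ctrl = matrix.samples_for("control", "exp1")
        log2 = np.log2(matrix.values)
        shared = list(truth.members(LABEL_SHARED))
        diffs = (log2.loc[shared, bait].mean(axis=1)
                 - log2.loc[shared, ctrl].mean(axis=1))
        se = cfg.replicate_sd_log2 * np.sqrt(2 / 100)
        assert np.all(np.abs(diffs - cfg.effect_size_log2) < 3 * se + 1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(px.ConfigurationError):
            px.SyntheticStudyConfig(n_proteins=-5).validate()
        with pytest.raises(px.ConfigurationError):
            px.SyntheticStudyConfig(replicate_sd_log2=0.0).validate()
        with pytest.raises(px.ConfigurationError):
            # planted interactors exceed the nuclear fraction
            px.SyntheticStudyConfig(n_proteins=100, frac_nuclear=0.1,
                                    n_true_shared=20).validate()


class TestAnnotationTables:
    def test_nuclear_list_and_known_mix(self, small_study):
        cfg, _, truth = small_study
        bundle = generate_annotation_tables(cfg, truth)
        assert bundle.nuclear.as_set == truth.nuclear
        assert set(bundle.known_planted) <= set(truth.planted_interactors)
        assert len(bundle.known) == 15  # 7 recoverable + 8 decoys
        assert set(bundle.known.members) <= truth.nuclear

    def test_full_nuclear_fraction_lists_all_proteins(self):
        cfg = px.SyntheticStudyConfig(n_proteins=60, frac_nuclear=1.0,
                                      n_true_shared=5, n_true_nt_only=0,
                                      n_true_ct_only=0, seed=2)
        _, truth = px.generate_abundance_study(cfg)
        bundle = generate_annotation_tables(
            cfg, truth, n_known_planted=3, n_known_decoys=3,
            disease_overlap={"sfari_like": 3, "dbd_like": 2},
            disease_shared=2)
        assert len(bundle.nuclear) == 60

    def test_known_request_exceeding_planted_errors(self, small_study):
        cfg, _, truth = small_study
        with pytest.raises(px.ValidationError):
            generate_annotation_tables(cfg, truth, n_known_planted=1000)

    def test_planted_disease_overlap_is_exact(self, small_study):
        cfg, _, truth = small_study
        bundle = generate_annotation_tables(cfg, truth)
        planted = px.GeneList("planted", tuple(truth.planted_interactors))
        mapped = px.map_orthologs(planted, bundle.orthologs).mapped
        for name, glist in bundle.disease.items():
            k_planted = len(bundle.planted_disease_overlap[name])
            observed = len(mapped.as_set & glist.as_set)
            assert observed == k_planted

    def test_low_score_orthologs_fail_strict_threshold(self, small_study):
        cfg, _, truth = small_study
        bundle = generate_annotation_tables(cfg, truth)
        rec = bundle.orthologs.records
        low = px.OrthologMap(records=rec[rec.score <= 8].reset_index(drop=True))
        res = px.map_orthologs(px.GeneList("all", tuple(truth.labels)), low,
                               min_score_exclusive=8)
        assert len(res.mapped) == 0


class TestPeakSets:
    def test_coincident_zero_offset_always_overlaps(self, toy_sizes):
        query, target = generate_peak_sets(
            toy_sizes, 40, 40, "coincident", offset_sd=0.0, seed=9,
            query_width=200, target_width=200)
        assert px.count_overlapping(query, target) == 40

    def test_flanking_bimodal_offsets(self, toy_sizes):
        query, target = generate_peak_sets(
            toy_sizes, 30, 30, "flanking_bimodal", seed=9, flank_offset=500,
            query_width=100, target_width=100)
        offsets = query.midpoints - target.midpoints
        assert set(np.abs(offsets)) == {500}

    def test_half_open_convention(self, toy_sizes):
        _, target = generate_peak_sets(toy_sizes, 5, 5, "independent", seed=1)
        assert np.all(target.starts < target.ends)
        target.validate_against(toy_sizes)

    def test_unfittable_width_errors(self):
        sizes = px.ChromSizes({"chr1": 50})
        with pytest.raises(px.ConfigurationError):
            generate_peak_sets(sizes, 3, 3, "independent", seed=0,
                               query_width=100, target_width=100)


class TestSignalTrack:
    def test_single_peak_track_values(self):
        sizes = px.ChromSizes({"chr1": 1000})
        peaks = px.PeakSet.from_intervals([("chr1", 100, 200)])
        track = generate_signal_track(peaks, 5.0, 1.0, sizes)
        # piecewise: [0,100)=1, [100,200)=5, [200,1000)=1
        assert track.integral("chr1", 100)[0] == pytest.approx(100.0)
        assert track.integral("chr1", 200)[0] == pytest.approx(100 + 500)
        assert track.total_mass == pytest.approx(100 + 500 + 800)

    def test_no_peaks_gives_constant_background(self):
        sizes = px.ChromSizes({"chr1": 500})
        track = generate_signal_track(
            px.PeakSet.from_intervals([("chr1", 1, 2)]), 2.0, 2.0, sizes)
        assert track.total_mass == pytest.approx(2.0 * 500)

    def test_mass_matches_direct_summation(self, toy_sizes):
        query, _ = generate_peak_sets(toy_sizes, 20, 20, "independent", seed=3,
                                      query_width=150)
        track = generate_signal_track(query, 7.0, 0.5, toy_sizes)
        # oracle: background * genome + (height - background) * union length
        union = 0
        for _, (s, e) in query.by_chrom().items():
            merged_end = -1
            for a, b in sorted(zip(s, e)):
                if a > merged_end:
                    union += b - a
                    merged_end = b
                elif b > merged_end:
                    union += b - merged_end
                    merged_end = b
        expected = 0.5 * toy_sizes.total + (7.0 - 0.5) * union
        assert track.total_mass == pytest.approx(expected)

    def test_height_below_background_errors(self, toy_sizes):
        peaks = px.PeakSet.from_intervals([("chr1", 0, 10)])
        with pytest.raises(px.ConfigurationError):
            generate_signal_track(peaks, 1.0, 2.0, toy_sizes)
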