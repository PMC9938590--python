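"""Differential-enrichment statistics: transform, normalize, impute, Welch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proxitome as px
from proxitome.enrichment import _welch_arrays

from oracles import welch_oracle


class TestTransformAndNormalize:
    def test_log2_maps_values_and_keeps_missing(self):
        m = pd.DataFrame({"s1": [8.0, 1.0], "s2": [np.nan, 4.0]},
                         index=["a", "b"])
        out = px.log2_transform(m)
        assert out.loc["a", "s1"] == 3.0
        assert out.loc["b", "s1"] == 0.0
        assert np.isnan(out.loc["a", "s2"])

    def test_hand_computed_normalization(self):
        # columns {0,2} and {10,12}: subtract column means 1 and 11,
        # add grand mean 6 -> both columns become {5,7}
        m = pd.DataFrame({"s1": [0.0, 2.0], "s2": [10.0, 12.0]})
        out = px.normalize_by_sample_mean(m)
        assert list(out["s1"]) == [5.0, 7.0]
        assert list(out["s2"]) == [5.0, 7.0]

    def test_column_means_equal_grand_mean(self, small_study):
        _, matrix, _ = small_study
        log2 = px.log2_transform(matrix.values)
        out = px.normalize_by_sample_mean(log2)
        grand = np.nanmean(log2.to_numpy())
        assert np.max(np.abs(out.mean(axis=0) - grand)) < 1e-9

    def test_empty_sample_errors_naming_sample(self):
        m = pd.DataFrame({"good": [1.0, 2.0], "empty": [np.nan, np.nan]})
        with pytest.raises(px.ValidationError, match="empty"):
            px.normalize_by_sample_mean(m)


class TestImputation:
    def test_no_missing_returns_unchanged_with_empty_mask(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out, mask = px.impute_missing(m, px.ImputationParams(seed=1))
        pd.testing.assert_frame_equal(out, m)
        assert not mask.to_numpy().any()

    def test_observed_cells_never_altered(self, small_study):
        _, matrix, _ = small_study
        log2 = px.normalize_by_sample_mean(px.log2_transform(matrix.values))
        out, mask = px.impute_missing(log2, px.ImputationParams(seed=3))
        observed = ~mask.to_numpy()
        np.testing.assert_array_equal(out.to_numpy()[observed],
                                      log2.to_numpy()[observed])
        assert not np.isnan(out.to_numpy()).any()

    def test_downshifted_moments_large_sample(self):
        # column whose present values have mean 20, SD 2 (ddof=1), plus
        # 10,000 missing cells: imputed draws ~ N(20 - 2*2, (0.3*2)^2)
        rng = np.random.default_rng(0)
        present = rng.normal(20, 2, 400)
        present = 20 + 2 * (present - present.mean()) / present.std(ddof=1)
        col = np.concatenate([present, np.full(10_000, np.nan)])
        m = pd.DataFrame({"s1": col})
        out, mask = px.impute_missing(m, px.ImputationParams(seed=9))
        draws = out.loc[mask["s1"], "s1"].to_numpy()
        assert len(draws) == 10_000
        assert abs(draws.mean() - 16.0) < 0.02
        assert abs(draws.std(ddof=1) - 0.6) < 0.02

    def test_seed_determinism(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, np.nan, np.nan, 3.0]})
        p = px.ImputationParams(seed=5)
        out1, _ = px.impute_missing(m, p)
        out2, _ = px.impute_missing(m, p)
        out3, _ = px.impute_missing(m, px.ImputationParams(seed=6))
        pd.testing.assert_frame_equal(out1, out2)
        assert not out1.equals(out3)

    def test_scope_with_too_few_present_errors(self):
        m = pd.DataFrame({"s1": [1.0, np.nan, np.nan]})
        with pytest.raises(px.ValidationError, match="s1"):
            px.impute_missing(m, px.ImputationParams(seed=1))


class TestWelch:
    def test_identical_groups(self):
        res = px.welch_ttest([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_against_integration_oracle(self):
        t, df, p = welch_oracle([1, 2, 3], [2, 4, 6])
        res = px.welch_ttest([1, 2, 3], [2, 4, 6])
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_symmetry(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        a, b = px.welch_ttest(x, y), px.welch_ttest(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.t == pytest.approx(-b.t)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_random_vectors_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 9, size=2)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), nx)
        y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), ny)
        t, df, p = welch_oracle(x, y)
        res = px.welch_ttest(x, y)
        assert res.p == pytest.approx(p, rel=1e-10, abs=1e-300)
        assert res.t == pytest.approx(t, rel=1e-10)

    def test_constant_unequal_groups_warn_and_p_zero(self):
        with pytest.warns(RuntimeWarning):
            res = px.welch_ttest([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.t == -np.inf


class TestRunComparison:
    def test_planted_interactor_power(self):
        # effect 2 log2 units, 4 vs 4 replicates, replicate SD 0.5:
        # the Welch test should call enrichment at p < 0.05 almost always
        rng = np.random.default_rng(123)
        n_sim, hits = 400, 0
        for _ in range(n_sim):
            x = rng.normal(22, 0.5, 4)
            y = rng.normal(20, 0.5, 4)
            t, df, p = _welch_arrays(x[None, :], y[None, :])
            hits += (p[0] < 0.05) and (x.mean() > y.mean())
        assert hits / n_sim >= 0.95

    def test_direction_required_for_enrichment(self, small_study):
        _, matrix, _ = small_study
        params = px.ImputationParams(seed=2)
        prepared = px.prepare_experiment(matrix, "exp1", params)
        spec = px.ComparisonSpec("nt_kdm5", "control", "exp1")
        res = px.run_comparison(prepared.complete, spec,
                                prepared.imputed_mask, prepared.metadata)
        flagged = res[res.enriched_05]
        assert (flagged.log2fc > 0).all()
        assert (flagged.pvalue < 0.05).all()

    def test_swapping_groups_negates_fc_keeps_p(self, small_study):
        _, matrix, _ = small_study
        params = px.ImputationParams(seed=2)
        prepared = px.prepare_experiment(matrix, "exp1", params)
        fwd = px.run_comparison(prepared.complete,
                                px.ComparisonSpec("nt_kdm5", "control", "exp1"),
                                prepared.imputed_mask, prepared.metadata)
        rev = px.run_comparison(prepared.complete,
                                px.ComparisonSpec("control", "nt_kdm5", "exp1"),
                                prepared.imputed_mask, prepared.metadata)
        common = fwd.index[fwd.excluded_reason == ""]
        common = [p for p in common if rev.loc[p, "excluded_reason"] == ""]
        np.testing.assert_allclose(fwd.loc[common, "log2fc"],
                                   -rev.loc[common, "log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd.loc[common, "pvalue"],
                                   rev.loc[common, "pvalue"], atol=1e-12)

    def test_all_missing_protein_excluded_not_tested(self):
        cfg = px.SyntheticStudyConfig(
            n_proteins=200, n_true_shared=10, n_true_nt_only=3,
            n_true_ct_only=3, n_background_biased=10, seed=8)
        matrix, _ = px.generate_abundance_study(cfg)
        # force one protein fully missing in exp1
        exp1 = matrix.samples_for(experiment="exp1")
        pid = matrix.values.index[0]
        matrix.values.loc[pid, exp1] = np.nan
        prepared = px.prepare_experiment(matrix, "exp1",
                                         px.ImputationParams(seed=1))
        assert pid in prepared.dropped_proteins
        assert pid not in prepared.complete.index

    def test_absent_condition_errors(self, small_study):
        _, matrix, _ = small_study
        prepared = px.prepare_experiment(matrix, "exp1",
                                         px.ImputationParams(seed=2))
        with pytest.raises(px.ValidationError, match="dcas9"):
            px.run_comparison(prepared.complete,
                              px.ComparisonSpec("nt_kdm5", "dcas9", "exp1"),
                              prepared.imputed_mask, prepared.metadata)

    def test_pipeline_is_reproducible_bit_exactly(self, small_study, six_specs):
        _, matrix, _ = small_study
        r1 = px.run_experiment_comparisons(matrix, six_specs,
                                           px.ImputationParams(seed=77))
        r2 = px.run_experiment_comparisons(matrix, six_specs,
                                           px.ImputationParams(seed=77))
        for slot in r1:
            pd.testing.assert_frame_equal(r1[slot], r2[slot])

    def test_fc_unbiased_for_planted_in_sparse_signal(self):
        # planted log2FC estimates center on the planted effect; the check
        # uses a sparse planted fraction because per-sample mean
        # normalization attenuates fold changes by roughly the fraction of
        # differential signal in the bait columns
        diffs = []
        for seed in range(20):
            cfg = px.SyntheticStudyConfig(
                n_proteins=400, n_true_shared=5, n_true_nt_only=0,
                n_true_ct_only=0, n_background_biased=0,
                missingness_midpoint_log2=0.0, seed=seed)
            matrix, truth = px.generate_abundance_study(cfg)
            prepared = px.prepare_experiment(matrix, "exp1",
                                             px.ImputationParams(seed=seed))
            res = px.run_comparison(
                prepared.complete, px.ComparisonSpec("nt_kdm5", "control", "exp1"),
                prepared.imputed_mask, prepared.metadata)
            diffs.extend(res.loc[list(truth.members("shared")), "log2fc"]
                         - cfg.effect_size_log2)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-3
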