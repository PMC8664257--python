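"""Preprocessing chain: depth filter, size factors, log transform, MNN."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from spherotime.preprocessing import (
    compute_size_factors,
    filter_low_depth,
    log_transform,
    mnn_batch_correct,
    moving_average,
    normalize_counts,
    preprocess,
)
from spherotime.synthetic import (
    ExpressionSimConfig,
    generate_expression_timecourse,
    inject_batch_effect,
)


class TestFilterLowDepth:
    def test_below_threshold_removed(self):
        m = make_matrix(np.ones((5, 2)), library_size=[6e6, 4.9e6])
        kept, removed = filter_low_depth(m, min_reads=5e6)
        assert removed == ["s1"]
        assert list(kept.sample_ids) == ["s0"]

    def test_all_pass_is_identity(self):
        m = make_matrix(np.ones((5, 3)), library_size=[6e6, 7e6, 8e6])
        kept, removed = filter_low_depth(m)
        assert removed == [] and kept.n_samples == 3

    def test_zero_threshold_is_identity(self):
        m = make_matrix(np.ones((5, 3)), library_size=[1.0, 2.0, 3.0])
        kept, removed = filter_low_depth(m, min_reads=0)
        assert removed == []

    def test_everything_removed_is_an_error(self):
        m = make_matrix(np.ones((5, 2)), library_size=[1e5, 2e5])
        with pytest.raises(ValueError):
            filter_low_depth(m)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, 40).astype(float)
        m = make_matrix(np.column_stack([col, col]))
        np.testing.assert_allclose(compute_size_factors(m), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 100, 40).astype(float)
        m = make_matrix(np.column_stack([col, 2 * col]))
        f = compute_size_factors(m)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)
        np.testing.assert_allclose(f.mean(), 1.0)

    def test_dominant_gene_is_excluded_from_factors(self):
        rng = np.random.default_rng(2)
        base = rng.integers(10, 50, (40, 3)).astype(float)
        loaded = base.copy()
        loaded[0, 0] = base.sum() * 9  # one gene, one sample, ~90% of reads
        f_loaded = compute_size_factors(make_matrix(loaded))
        # direct-sum oracle over the non-top-5% genes
        mean_expr = loaded.mean(axis=1)
        included = mean_expr < np.percentile(mean_expr, 95)
        assert not included[0]  # the dominant gene sits in the excluded set
        sums = loaded[included].sum(axis=0)
        np.testing.assert_allclose(f_loaded, sums / sums.mean(), rtol=1e-12)
        # rescaling an excluded gene leaves the factors unchanged
        rescaled = loaded.copy()
        rescaled[0] *= 3.0
        np.testing.assert_allclose(
            compute_size_factors(make_matrix(rescaled)), f_loaded, rtol=1e-12
        )

    def test_zero_count_sample_rejected(self):
        m = make_matrix(np.column_stack([np.ones(10), np.zeros(10)]))
        with pytest.raises(ValueError):
            compute_size_factors(m)


class TestNormalizeCounts:
    def test_unit_factors_give_plain_cpm_shape(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(1, 100, (30, 4)).astype(float)
        vals = vals / vals.sum(axis=0) * 1e6  # equal library sizes
        m = make_matrix(vals)
        out = normalize_counts(m, pd.Series(1.0, index=m.sample_ids))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6)

    def test_scaling_sample_and_factor_together_is_invariant(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 100, (30, 2)).astype(float)
        m1 = make_matrix(vals)
        f1 = compute_size_factors(m1)
        vals2 = vals.copy()
        vals2[:, 1] *= 2
        m2 = make_matrix(vals2)
        f2 = f1 * [1.0, 2.0]
        n1 = normalize_counts(m1, f1).values.to_numpy()
        n2 = normalize_counts(m2, f2).values.to_numpy()
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_column_sums_over_included_genes_equalize(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 200, (60, 5)).astype(float)
        m = make_matrix(vals)
        f = compute_size_factors(m)
        out = normalize_counts(m, f)
        mean_expr = vals.mean(axis=1)
        included = mean_expr < np.percentile(mean_expr, 95)
        sums = out.values.to_numpy()[included].sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_non_positive_factor_rejected(self):
        m = make_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            normalize_counts(m, pd.Series([1.0, 0.0], index=m.sample_ids))


class TestLogTransform:
    @pytest.mark.parametrize("x,expected", [(0.0, 3.0), (8.0, 4.0), (24.0, 5.0)])
    def test_pseudocount_eight_fixed_points(self, x, expected):
        m = make_matrix(np.full((2, 2), x), scale="normalized")
        out = log_transform(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_order_statistics_preserved(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 500, (20, 6))
        m = make_matrix(vals, scale="normalized")
        out = log_transform(m).values.to_numpy()
        for g in range(20):
            np.testing.assert_array_equal(np.argsort(out[g]), np.argsort(vals[g]))

    def test_negative_input_rejected(self):
        m = make_matrix(np.ones((2, 2)), scale="normalized")
        m.values.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            log_transform(m)


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(10, 2.5), 4), 2.5)

    def test_truncated_centered_window_matches_sliding_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        got = moving_average(x, 2)
        # window [i, i+1] truncated at the right edge
        np.testing.assert_allclose(got, [1.5, 2.5, 3.5, 4.0])
        rng = np.random.default_rng(7)
        y = rng.normal(size=23)
        for w in [2, 3, 5, 8]:
            lo = (w - 1) // 2
            hi = w - 1 - lo
            oracle = np.array(
                [y[max(0, i - lo): min(len(y), i + hi + 1)].mean()
                 for i in range(len(y))]
            )
            np.testing.assert_allclose(moving_average(y, w), oracle, rtol=1e-12)

    def test_window_larger_than_series_gives_global_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(moving_average(x, 10), x.mean())

    def test_2d_applies_along_columns(self):
        X = np.vstack([np.arange(6.0), np.arange(6.0) * 2])
        out = moving_average(X, 3)
        np.testing.assert_allclose(out[1], moving_average(X[1], 3))


class TestMnnBatchCorrect:
    @staticmethod
    def bridged_matrix(shift=0.0, n_genes=50, seed=0):
        """Batch B duplicates batch A's bridge samples plus a constant shift."""
        rng = np.random.default_rng(seed)
        base = rng.normal(8.0, 1.0, (n_genes, 6))
        va = base
        vb = base + shift
        values = np.hstack([va, vb])
        ct = [10, 10, 11, 11, 10, 11] + [12, 12, 13, 13, 12, 13]
        m = make_matrix(values, collection_time=ct, scale="log2")
        m.samples["batch"] = ["A"] * 6 + ["B"] * 6
        return m

    def test_constant_shift_recovered_exactly(self):
        m = self.bridged_matrix(shift=1.0)
        corrected, shifts = mnn_batch_correct(m)
        np.testing.assert_allclose(shifts.shifts, 1.0, atol=1e-12)
        va = corrected.values.to_numpy()[:, :6]
        vb = corrected.values.to_numpy()[:, 6:]
        np.testing.assert_allclose(va, vb, atol=1e-12)

    def test_zero_shift_gives_near_zero_correction(self):
        m = self.bridged_matrix(shift=0.0)
        corrected, shifts = mnn_batch_correct(m)
        np.testing.assert_allclose(shifts.shifts, 0.0, atol=1e-12)
        pd.testing.assert_frame_equal(corrected.values, m.values)

    def test_random_shifts_recovered_on_synthetic_course(self):
        cfg = ExpressionSimConfig(
            n_genes=200, n_dynamic=30, n_condition_divergent=0,
            n_samples_per_condition=110, dispersion=0.02, batch_shift_sd=0.0,
            seed=21,
        )
        matrix, _ = generate_expression_timecourse(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logm, _ = preprocess(matrix, batch_correct=False)
        rng = np.random.default_rng(22)
        shifts = pd.Series(
            np.where(rng.random(logm.n_genes) < 0.2,
                     rng.normal(0, 0.5, logm.n_genes), 0.0),
            index=logm.gene_ids,
        )
        shifted = inject_batch_effect(logm, shifts, logm.samples["batch"])
        corrected, est = mnn_batch_correct(shifted)
        affected = shifts[shifts != 0].index
        resid = (est.shifts - shifts).loc[affected].abs().mean()
        assert shifts.loc[affected].abs().mean() >= 0.3
        assert resid < shifts.loc[affected].abs().mean() / 2

    def test_empty_bridge_set_rejected(self):
        m = self.bridged_matrix()
        m.samples["collection_time"] = 1.0
        with pytest.raises(ValueError, match="bridge"):
            mnn_batch_correct(m)

    def test_log_scale_required(self):
        m = make_matrix(np.ones((5, 4)))
        with pytest.raises(ValueError, match="log2"):
            mnn_batch_correct(m)


class TestFullChain:
    def test_noise_free_flat_course_is_reproduced_exactly(self):
        """Without count noise or dynamics, the chain returns log2(CPM + 8)
        exactly (size factors recover the library sizes)."""
        cfg = ExpressionSimConfig(
            n_genes=80, n_dynamic=0, n_condition_divergent=0,
            n_samples_per_condition=44, dispersion=0.0, asynchrony_sd=0.0,
            batch_shift_sd=0.0, trajectory_family="flat", seed=13,
        )
        matrix, truth = generate_expression_timecourse(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logm, _ = preprocess(matrix, batch_correct=False)
        want = np.log2(2.0 ** truth.expected_log2_cpm.to_numpy() + 8.0)
        np.testing.assert_allclose(logm.values.to_numpy(), want, rtol=1e-9)

    def test_noise_free_dynamic_course_constant_per_sample_scale(self):
        """With dynamic genes the estimated size factors absorb compositional
        drift: the recovered CPM differs from truth by one scale per sample."""
        cfg = ExpressionSimConfig(
            n_genes=80, n_dynamic=20, n_condition_divergent=0,
            n_samples_per_condition=44, dispersion=0.0, asynchrony_sd=0.0,
            batch_shift_sd=0.0, seed=13,
        )
        matrix, truth = generate_expression_timecourse(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logm, _ = preprocess(matrix, batch_correct=False)
        got = 2.0 ** logm.values.to_numpy() - 8.0  # back to CPM-like scale
        want = 2.0 ** truth.expected_log2_cpm.to_numpy()
        ratio = got / want
        spread = ratio.max(axis=0) / ratio.min(axis=0) - 1.0
        assert spread.max() < 1e-9
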