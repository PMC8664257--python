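"""Differential dynamics: alignment, delta test, effects, clusters, qPCR."""

import numpy as np
import pandas as pd
import pytest

from spherotime.dynamics import (
    align_series,
    cluster_profiles,
    delta_gam_test,
    effect_size,
    intron_exon_trajectory,
    relative_expression_ddct,
    select_affected_genes,
    transcription_shutoff_point,
)


def series_frame(values, prefix="s"):
    values = np.atleast_2d(values)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestAlignSeries:
    def test_identical_series_have_zero_delta(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 22, 40))
        vals = rng.normal(5, 1, (6, 40))
        pair = align_series(series_frame(vals), t, series_frame(vals, "u"), t,
                            n_points=30)
        np.testing.assert_allclose(pair.delta.to_numpy(), 0.0, atol=1e-12)

    def test_linear_profiles_interpolate_exactly(self):
        ta = np.array([0.0, 10.0, 22.0])
        tb = np.array([0.0, 5.0, 22.0])
        a = series_frame(2.0 * ta + 1.0)
        b = series_frame(2.0 * tb + 1.0, "u")
        pair = align_series(a, ta, b, tb, n_points=50)
        np.testing.assert_allclose(
            pair.series_a.to_numpy()[0], 2.0 * pair.grid + 1.0, atol=1e-12
        )
        np.testing.assert_allclose(pair.delta.to_numpy(), 0.0, atol=1e-12)

    def test_downsampling_matches_numpy_interp_oracle(self):
        rng = np.random.default_rng(1)
        ta = np.sort(rng.uniform(0, 22, 300))
        tb = np.sort(rng.uniform(0, 22, 150))
        a = series_frame(rng.normal(size=(3, 300)))
        b = series_frame(rng.normal(size=(3, 150)), "u")
        pair = align_series(a, ta, b, tb, n_points=150)
        for g in range(3):
            ref = np.interp(pair.grid, ta, a.to_numpy()[g])
            np.testing.assert_allclose(pair.series_a.to_numpy()[g], ref, atol=1e-12)

    def test_grid_spans_range_intersection(self):
        ta = np.linspace(0, 20, 30)
        tb = np.linspace(5, 25, 30)
        rng = np.random.default_rng(2)
        pair = align_series(series_frame(rng.normal(size=(2, 30))), ta,
                            series_frame(rng.normal(size=(2, 30)), "u"), tb)
        assert pair.grid[0] == pytest.approx(5.0)
        assert pair.grid[-1] == pytest.approx(20.0)

    def test_disjoint_ranges_rejected(self):
        ta = np.linspace(0, 5, 10)
        tb = np.linspace(10, 15, 10)
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="overlap"):
            align_series(series_frame(rng.normal(size=(1, 10))), ta,
                         series_frame(rng.normal(size=(1, 10)), "u"), tb)


class TestDeltaGamTest:
    def test_constant_offset_is_not_a_shape_change(self):
        """The smooth term tests shape, not offset; a constant delta is left
        for the effect size to catch."""
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 22, 120))
        base = rng.normal(5, 1, (1, 120))
        pair = align_series(series_frame(base), t,
                            series_frame(base + 0.8, "u"), t, n_points=100)
        table = delta_gam_test(pair)
        assert table["smooth_p"].iloc[0] > 0.5

    def test_zero_variance_delta_flagged_with_p_one(self):
        t = np.linspace(0, 22, 50)
        vals = series_frame(np.tile(np.sin(t / 3), (2, 1)))
        pair = align_series(vals, t, vals.rename(columns=lambda c: "u" + c), t)
        table = delta_gam_test(pair)
        assert table["zero_variance"].all()
        np.testing.assert_allclose(table["smooth_p"], 1.0)

    def test_shape_divergence_is_detected(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 22, 150))
        a = series_frame(np.sin(t / 4) + rng.normal(0, 0.1, 150))
        b = series_frame(np.sin(t / 4) + np.where(t > 15, t - 15, 0.0) * 0.5
                         + rng.normal(0, 0.1, 150), "u")
        pair = align_series(a, t, b, t)
        assert delta_gam_test(pair)["p_adjusted"].iloc[0] < 1e-6


class TestEffectSize:
    def test_identical_signals_have_zero_effect(self):
        t = np.linspace(0, 22, 60)
        vals = series_frame(np.sin(t / 3))
        pair = align_series(vals, t, vals.rename(columns=lambda c: "u" + c), t)
        assert effect_size(pair).iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_centred_difference_sums_over_included_points(self):
        # after mean-centring, a pure offset cancels; build series whose
        # centred difference is exactly 0.5 at every point instead
        n = 150
        grid_vals_a = np.concatenate([np.zeros(75), np.ones(75)])
        grid_vals_b = np.concatenate([np.zeros(75), np.ones(75) * 2.0])
        t = np.linspace(0, 22, n)
        pair = align_series(series_frame(grid_vals_a), t,
                            series_frame(grid_vals_b, "u"), t, n_points=n)
        # centred difference: +/-0.5 at every grid point -> sum over 147
        assert effect_size(pair).iloc[0] == pytest.approx(147 * 0.5)

    def test_offsetting_one_condition_changes_nothing(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 22, 80))
        a = series_frame(rng.normal(size=(4, 80)))
        b = series_frame(rng.normal(size=(4, 80)), "u")
        p1 = align_series(a, t, b, t)
        p2 = align_series(a, t, b + 3.7, t)
        np.testing.assert_allclose(effect_size(p1), effect_size(p2), rtol=1e-9)


class TestSelectAffectedGenes:
    @staticmethod
    def table(p, eff):
        return pd.DataFrame(
            {"p_adjusted": p, "effect_size": eff},
            index=[f"g{i:03d}" for i in range(len(p))],
        )

    def test_flag_combinations(self):
        t = select_affected_genes(self.table([1e-7, 1e-7, 0.5], [50.0, 10.0, 50.0]))
        assert t["passes_significance"].tolist() == [True, True, False]
        assert t["passes_effect"].tolist() == [True, False, True]

    def test_top_fraction_counts_and_tie_break(self):
        p = [1e-8] * 100
        eff = [50.0] * 100  # all tied: lexicographic gene order decides
        t = select_affected_genes(self.table(p, eff))
        assert int(t["top_flag"].sum()) == 10
        assert t.index[t["top_flag"]].tolist() == [f"g{i:03d}" for i in range(10)]

    def test_top_flags_subset_of_significant(self):
        rng = np.random.default_rng(7)
        t = select_affected_genes(
            self.table(rng.uniform(0, 1, 50) ** 6, rng.uniform(0, 100, 50))
        )
        assert not (t["top_flag"] & ~t["passes_significance"]).any()


class TestClusterProfiles:
    def test_two_separated_families_split_perfectly(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 40)
        up = np.vstack([t * 2 + rng.normal(0, 0.05, 40) for _ in range(15)])
        down = np.vstack([-t * 2 + rng.normal(0, 0.05, 40) for _ in range(15)])
        profiles = pd.DataFrame(np.vstack([up, down]))
        labels = cluster_profiles(profiles, k=2, seed=0)
        assert labels.iloc[:15].nunique() == 1
        assert labels.iloc[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_profiles_have_zero_inertia(self):
        profiles = pd.DataFrame(np.tile(np.arange(10.0), (8, 1)))
        labels = cluster_profiles(profiles, k=2, seed=0)
        assert labels.nunique() <= 2  # degenerate split of identical points

    def test_same_seed_same_assignment(self):
        rng = np.random.default_rng(9)
        profiles = pd.DataFrame(rng.normal(size=(30, 20)))
        a = cluster_profiles(profiles, k=5, seed=3)
        b = cluster_profiles(profiles, k=5, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_more_clusters_than_genes_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame(np.ones((3, 5))), k=5)


class TestIntronExonTrajectory:
    def test_baseline_intron_with_decaying_exon_is_degradation(self):
        n = 200
        intr = np.full(n, 0.1)
        exon = np.exp(-np.linspace(0, 3, n))
        traj = intron_exon_trajectory(intr, exon, window=20)
        assert (traj["phase"] == "degradation").mean() > 0.9

    def test_proportional_rise_is_transcription(self):
        n = 200
        ramp = np.linspace(0, 1, n)
        traj = intron_exon_trajectory(ramp, ramp * 2, window=20)
        assert (traj["phase"] == "transcription").mean() > 0.9

    def test_two_phase_gene_changepoint_recovered(self):
        """Transcription on -> off with first-order mRNA decay: the shutoff
        point is recovered within +/- 5 grid points."""
        n = 150
        off = 90
        intr = np.where(np.arange(n) < off, 1.0, 0.02)
        exon = np.empty(n)
        exon[0] = 0.0
        for i in range(1, n):  # dm/dt = k_tx * intron - k_deg * m
            exon[i] = exon[i - 1] + 0.15 * intr[i - 1] - 0.05 * exon[i - 1]
        traj = intron_exon_trajectory(intr, exon, window=36)
        cp = transcription_shutoff_point(traj)
        assert cp is not None and abs(cp - off) <= 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intron_exon_trajectory(np.ones(10), np.ones(11))


class TestRelativeExpressionDdct:
    def test_calibrator_sample_is_fold_one(self):
        ct_t = pd.Series({"t0": 25.0, "t1": 24.0}, dtype=float)
        ct_r = pd.Series({"t0": 20.0, "t1": 20.0}, dtype=float)
        fc = relative_expression_ddct(ct_t, ct_r, "t0")
        assert fc["t0"] == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        ct_t = pd.Series({"t0": 25.0, "t1": 24.0})
        ct_r = pd.Series({"t0": 20.0, "t1": 20.0})
        fc = relative_expression_ddct(ct_t, ct_r, "t0")
        assert fc["t1"] == pytest.approx(2.0)

    def test_two_cycles_later_quarters_expression(self):
        ct_t = pd.Series({"t0": 25.0, "t1": 27.0})
        ct_r = pd.Series({"t0": 20.0, "t1": 20.0})
        fc = relative_expression_ddct(ct_t, ct_r, "t0")
        assert fc["t1"] == pytest.approx(0.25)

    def test_missing_reference_rejected(self):
        ct_t = pd.Series({"t0": 25.0, "t1": 24.0})
        ct_r = pd.Series({"t0": 20.0})
        with pytest.raises(ValueError, match="missing reference"):
            relative_expression_ddct(ct_t, ct_r, "t0")
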