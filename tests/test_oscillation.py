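"""Oscillation quantification: cycles, transitions, areas, images, stats."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spherotime.containers import RadiusTrace
from spherotime.oscillation import (
    Cycle,
    CycleTable,
    detect_cycles,
    detect_phase_transition,
    fit_inflation_slope,
    measure_tissue_thickness,
    moods_median_test,
    phase1_area,
    segment_spheroid_image,
    wilcoxon_rank_sum,
)
from spherotime.synthetic import (
    OscillationSimConfig,
    generate_oscillation_trace,
    generate_spheroid_image,
)

SAWTOOTH = OscillationSimConfig(
    n_cycles_phase1=4, n_cycles_phase2=0, slope=0.0625,
    rupture_threshold=1.5, deflation_floor=1.0, noise_sd=0.0,
)


def make_table(amplitudes, periods):
    cycles = [
        Cycle(10 * i, 10 * i + 5, 10 * (i + 1), slope=a / p, amplitude=a, period=p)
        for i, (a, p) in enumerate(zip(amplitudes, periods))
    ]
    return CycleTable(cycles=cycles)


class TestDetectCycles:
    def test_flat_trace_has_no_cycles(self):
        trace = RadiusTrace(np.arange(0, 10, 0.1), np.ones(100))
        assert detect_cycles(trace).n_cycles == 0

    def test_noise_free_sawtooth_metrics_exact(self):
        table = detect_cycles(generate_oscillation_trace(SAWTOOTH))
        assert table.n_cycles == 4
        np.testing.assert_allclose(table.slopes, 0.0625, atol=1e-9)
        np.testing.assert_allclose(table.amplitudes, 0.5, atol=1e-9)
        np.testing.assert_allclose(table.periods, 8.0, atol=1e-9)

    def test_noisy_sawtooth_cycle_count_recovered(self):
        hits = 0
        for seed in range(50):
            cfg = OscillationSimConfig(
                n_cycles_phase1=4, n_cycles_phase2=0, noise_sd=0.01, seed=seed
            )
            hits += detect_cycles(generate_oscillation_trace(cfg)).n_cycles == 4
        assert hits >= 48  # >= 95% of runs

    def test_monotone_rise_yields_no_cycle(self):
        t = np.arange(0, 20, 1 / 6)
        trace = RadiusTrace(t, 1.0 + 0.02 * t)
        assert detect_cycles(trace).n_cycles == 0


class TestPhaseTransition:
    def test_transition_requires_both_criteria(self):
        # amplitude drop + frequency doubling -> cycle 3
        assert detect_phase_transition(
            make_table([0.50, 0.48, 0.20, 0.19], [8, 8, 3.5, 3.5])
        ) == 3
        # amplitude decay alone never transitions
        assert detect_phase_transition(
            make_table([0.5, 0.45, 0.4], [8, 8, 8])
        ) is None
        # amplitude halves but the period does not -> still phase I
        assert detect_phase_transition(make_table([0.5, 0.2], [8, 8])) is None

    def test_fewer_than_two_cycles_gives_none(self):
        assert detect_phase_transition(make_table([0.5], [8])) is None

    def test_shrinking_a_phase2_cycle_never_undetects(self):
        base = detect_phase_transition(
            make_table([0.5, 0.5, 0.2], [8.0, 8.0, 3.9])
        )
        assert base == 3
        for amp in [0.15, 0.1, 0.05]:
            for per in [3.5, 3.0, 2.0]:
                assert detect_phase_transition(
                    make_table([0.5, 0.5, amp], [8.0, 8.0, per])
                ) == 3

    def test_detection_on_simulated_phase_switch(self):
        cfg = OscillationSimConfig(
            phase2_amplitude_factor=0.5, phase2_period_factor=0.5, noise_sd=0.0
        )
        table = detect_cycles(generate_oscillation_trace(cfg))
        assert detect_phase_transition(table) == 5  # first phase-II cycle


class TestPhase1Area:
    def test_flat_trace_zero_area(self):
        trace = RadiusTrace(np.arange(0, 5, 0.1), np.ones(50))
        assert phase1_area(trace, detect_cycles(trace)) == 0.0

    def test_single_triangular_cycle_area(self):
        cfg = OscillationSimConfig(n_cycles_phase1=1, n_cycles_phase2=0, noise_sd=0.0)
        trace = generate_oscillation_trace(cfg)
        area = phase1_area(trace, detect_cycles(trace))
        assert area == pytest.approx(2.0, rel=1e-9)

    def test_two_cycles_area_is_additive(self):
        cfg = OscillationSimConfig(n_cycles_phase1=2, n_cycles_phase2=0, noise_sd=0.0)
        trace = generate_oscillation_trace(cfg)
        area = phase1_area(trace, detect_cycles(trace))
        assert area == pytest.approx(4.0, rel=1e-9)

    def test_area_invariant_under_time_translation(self):
        cfg = OscillationSimConfig(n_cycles_phase1=2, n_cycles_phase2=0, noise_sd=0.0)
        trace = generate_oscillation_trace(cfg)
        shifted = RadiusTrace(trace.time + 13.0, trace.radius.copy())
        a0 = phase1_area(trace, detect_cycles(trace))
        a1 = phase1_area(shifted, detect_cycles(shifted))
        assert a1 == pytest.approx(a0, rel=1e-12)

    def test_negative_excursions_clipped(self):
        t = np.arange(0, 4, 0.5)
        trace = RadiusTrace(t, np.array([1.0, 0.5, 0.5, 0.5, 1.0, 1.5, 1.5, 1.0]))
        area = phase1_area(trace, CycleTable())
        # only the part above 1.0 counts: trapezoids over [2, 3.5]
        assert area == pytest.approx(0.125 + 0.25 + 0.125)


class TestInflationSlope:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, ci = fit_inflation_slope(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert ci[1] - ci[0] == pytest.approx(0.0, abs=1e-9)

    def test_constant_y_gives_zero_slope(self):
        slope, _, _ = fit_inflation_slope(np.arange(5.0), np.full(5, 3.0))
        assert slope == pytest.approx(0.0)

    def test_noisy_line_ci_covers_truth(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 100)
        slope, _, (lo, hi) = fit_inflation_slope(x, x + rng.normal(0, 0.1, 100))
        assert lo < 1.0 < hi

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_inflation_slope(np.ones(5), np.arange(5.0))


class TestMoodsMedian:
    def test_separated_groups_match_contingency_oracle(self):
        a, b = [1, 2, 3, 4], [5, 6, 7, 8]
        stat, p = moods_median_test(a, b)
        ref = stats.chi2_contingency(np.array([[4, 0], [0, 4]]), correction=True)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_groups_not_significant(self):
        _, p = moods_median_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p == pytest.approx(1.0)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            moods_median_test([2, 2, 2], [2, 2, 2])

    def test_matches_scipy_median_test(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=n) for n in (12, 15, 9)]
        stat, p = moods_median_test(*groups)
        ref = stats.median_test(*groups, ties="below", correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_rejection_rate_calibrated(self):
        """Three same-distribution groups: alpha close to nominal 0.05."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            g = [rng.normal(size=50) for _ in range(3)]
            hits += moods_median_test(*g)[1] < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= hits <= hi


def rank_sum_oracle(a, b):
    """Exhaustive permutation distribution of the midrank sum."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    p = 2 * min((sums <= w + 1e-9).mean(), (sums >= w - 1e-9).mean())
    return w, min(1.0, p)


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 5], [1, 2, 5])
        assert p == pytest.approx(1.0)

    def test_two_vs_two_exact_third(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2], [3, 4]),
            ([1, 1, 2], [2, 3]),
            ([5, 1, 3], [2, 4, 6, 8]),
            ([0, 0, 0, 1], [1, 1, 2, 2]),
            ([1.5, 2.5], [1.5, 2.5, 3.5]),
            ([10], [1, 2, 3, 4, 5, 6, 7]),
        ],
    )
    def test_matches_enumeration_oracle(self, a, b):
        w, p = wilcoxon_rank_sum(a, b)
        w_ref, p_ref = rank_sum_oracle(np.asarray(a, float), np.asarray(b, float))
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
    )
    def test_property_matches_oracle_with_ties(self, a, b):
        w, p = wilcoxon_rank_sum(a, b)
        w_ref, p_ref = rank_sum_oracle(np.asarray(a, float), np.asarray(b, float))
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    def test_large_sample_calibration(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            hits += wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= hits <= hi


class TestSegmentation:
    def test_disk_area_recovered_within_two_percent(self):
        # 130 um outer radius at 1.3 um/px = 100 px
        img = generate_spheroid_image(100, 80, image_size=360, noise_sd=0.05, seed=2)
        res = segment_spheroid_image(img, pixel_size=1.3)
        true_area = np.pi * 130.0**2
        assert res.found
        assert abs(res.area_um2 - true_area) / true_area < 0.02

    def test_sub_threshold_object_rejected(self):
        # area 4000 um^2 -> radius ~27.5 px at 1.3 um/px: below the 5000 um^2 cut
        img = generate_spheroid_image(27.5, 0, image_size=300, noise_sd=0.02, seed=3)
        res = segment_spheroid_image(img, pixel_size=1.3)
        assert not res.found and res.area_um2 == 0.0

    def test_blank_image_finds_nothing(self):
        rng = np.random.default_rng(0)
        blank = 0.85 + rng.normal(0, 0.05, (300, 300))
        assert not segment_spheroid_image(blank, pixel_size=1.3).found

    def test_multichannel_input_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            segment_spheroid_image(np.zeros((64, 64, 3)), pixel_size=1.3)


class TestTissueThickness:
    @staticmethod
    def ring_image(outer, inner, size=320, noise=0.0, seed=0):
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(yy - c, xx - c)
        img = np.where((r <= outer) & (r > inner), 1.0, 0.05)
        if noise:
            img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
        return img

    def test_ideal_annulus_thickness(self):
        # areas 400*pi and 100*pi px^2 -> radii 20 and 10 -> thickness 10
        th = measure_tissue_thickness(self.ring_image(20, 10, size=96))
        assert th == pytest.approx(10.0, abs=1.0)

    def test_generated_spheroid_ring(self):
        img = 1.0 - generate_spheroid_image(100, 80, 320, noise_sd=0.02, seed=1)
        th = measure_tissue_thickness(img)
        assert th == pytest.approx(20.0, abs=2.0)

    def test_filled_disk_has_no_lumen(self):
        with pytest.raises(ValueError, match="lumen"):
            measure_tissue_thickness(self.ring_image(30, 0, size=128))
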