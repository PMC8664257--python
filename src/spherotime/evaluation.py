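"""Benchmark drivers: parameter-recovery and calibration studies.

Each function regenerates its synthetic inputs, runs the relevant pipeline
stage and measures recovery or calibration.  The same drivers back the
acceptance test suite and the standalone acceptance script, so the numbers
reported by both are computed identically.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RadiusTrace
from .dynamics import DifferentialDynamics
from .oscillation import (
    detect_cycles,
    detect_phase_transition,
    moods_median_test,
    phase1_area,
    segment_spheroid_image,
    wilcoxon_rank_sum,
)
from .preprocessing import mnn_batch_correct, preprocess
from .projection import fit_segment_basis
from .pseudotime import PseudotimeModel
from .synthetic import (
    ExpressionSimConfig,
    OscillationSimConfig,
    generate_expression_timecourse,
    generate_oscillation_trace,
    generate_segment_profiles,
    generate_spheroid_image,
    inject_batch_effect,
)

__all__ = [
    "pseudotime_recovery",
    "batch_shift_recovery",
    "oscillation_metrics",
    "triangle_area",
    "differential_calibration",
    "divergence_power",
    "projection_oracle_error",
    "stats_oracle_error",
    "stats_alpha_calibration",
    "segmentation_accuracy",
    "gam_null_calibration",
]


from contextlib import contextmanager


@contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def pseudotime_recovery(seed: int = 1, noise_free: bool = False) -> dict:
    """Spearman correlation of consensus pseudotime with latent time.

    Study conditions: 150 samples per condition, 400 genes (60 dynamic),
    asynchrony sd 1.5 h, NB dispersion 0.1 (0 in the noise-free limit).
    The ordering runs on the control condition after full preprocessing.
    """
    cfg = ExpressionSimConfig(
        dispersion=0.0 if noise_free else 0.1,
        batch_shift_sd=0.0,
        seed=seed,
    )
    matrix, truth = generate_expression_timecourse(cfg)
    ctrl = matrix.sample_ids[matrix.samples["condition"] == "control"]
    with _quiet():
        logm, _ = preprocess(matrix.subset_samples(ctrl), batch_correct=False)
        res = PseudotimeModel(logm).fit(seed=seed)
    rho = stats.spearmanr(
        res.pseudotime, truth.latent_time.loc[res.pseudotime.index]
    ).statistic
    _, med_spread = res.median_collection_spread()
    return {
        "rho": float(rho),
        "median_spread_h": float(med_spread),
        "n_samples": int(len(res.pseudotime)),
    }


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def batch_shift_recovery(seed: int = 1) -> dict:
    """Inject N(0, 0.5) log2 shifts on 20% of genes; measure the residual.

    Shifts are injected in log2 space on the second collection session of
    the full two-condition matrix and re-estimated with the top-3 Spearman
    MNN bridge procedure; the residual is the mean absolute difference of
    estimated and injected shift over the affected genes.
    """
    cfg = ExpressionSimConfig(batch_shift_sd=0.0, seed=seed)
    matrix, _ = generate_expression_timecourse(cfg)
    with _quiet():
        logm, _ = preprocess(matrix, batch_correct=False)
    rng = np.random.default_rng(seed + 1)
    affected = rng.random(logm.n_genes) < 0.2
    shifts = pd.Series(
        np.where(affected, rng.normal(0.0, 0.5, logm.n_genes), 0.0),
        index=logm.gene_ids,
    )
    shifted = inject_batch_effect(logm, shifts, logm.samples["batch"])
    with _quiet():
        corrected, est = mnn_batch_correct(shifted)
    aff_ids = shifts[shifts != 0].index
    return {
        "mean_abs_residual": float((est.shifts - shifts).loc[aff_ids].abs().mean()),
        "mean_abs_uncorrected": float(shifts.loc[aff_ids].abs().mean()),
        "n_mnn_pairs": est.n_pairs,
        "n_affected_genes": int(len(aff_ids)),
    }


# ---------------------------------------------------------------------------
# oscillations
# ---------------------------------------------------------------------------

SAWTOOTH = dict(
    n_cycles_phase1=4, n_cycles_phase2=0, slope=0.0625,
    rupture_threshold=1.5, deflation_floor=1.0,
)


def oscillation_metrics(seed: int = 1, n_traces: int = 50) -> dict:
    """Sawtooth metric exactness and noisy cycle-count recovery."""
    table = detect_cycles(
        generate_oscillation_trace(OscillationSimConfig(**SAWTOOTH, noise_sd=0.0))
    )
    slope_err = float(np.max(np.abs(table.slopes - 0.0625)))
    amp_err = float(np.max(np.abs(table.amplitudes - 0.5)))
    per_err = float(np.max(np.abs(table.periods - 8.0)))

    hits = 0
    for i in range(n_traces):
        cfg = OscillationSimConfig(**SAWTOOTH, noise_sd=0.01, seed=seed * 1000 + i)
        hits += detect_cycles(generate_oscillation_trace(cfg)).n_cycles == 4

    # halved amplitude + halved period switches the regime at cycle 5
    switch = OscillationSimConfig(
        phase2_amplitude_factor=0.5, phase2_period_factor=0.5, noise_sd=0.0
    )
    transition = detect_phase_transition(
        detect_cycles(generate_oscillation_trace(switch))
    )
    return {
        "max_metric_error": max(slope_err, amp_err, per_err),
        "noisy_count_recovery": hits / n_traces,
        "transition_index": transition,
        "n_traces": n_traces,
    }


def triangle_area() -> float:
    """Phase-I area of a single 1.0 -> 1.5 rise over 8 h (truth: 2.0)."""
    cfg = OscillationSimConfig(n_cycles_phase1=1, n_cycles_phase2=0, noise_sd=0.0)
    trace = generate_oscillation_trace(cfg)
    return float(phase1_area(trace, detect_cycles(trace)))


# ---------------------------------------------------------------------------
# differential dynamics
# ---------------------------------------------------------------------------

def _null_pair(seed: int, n_genes: int = 500):
    cfg = ExpressionSimConfig(
        n_genes=n_genes, n_dynamic=n_genes * 15 // 100, n_condition_divergent=0,
        batch_shift_sd=0.0, seed=seed,
    )
    matrix, truth = generate_expression_timecourse(cfg)
    with _quiet():
        logm, _ = preprocess(matrix, batch_correct=False)
    ids_a = logm.sample_ids[logm.samples["condition"] == "control"]
    ids_b = logm.sample_ids[logm.samples["condition"] == "isotonic"]
    pt = truth.latent_time
    return logm, list(ids_a), list(ids_b), pt


def differential_calibration(seed: int = 1, n_reps: int = 20) -> dict:
    """Null replicates (identical generators): count clean replicates.

    A replicate is clean when no gene passes both the FDR cut (1e-6) and the
    effect cut (40).
    """
    clean = 0
    for rep in range(n_reps):
        logm, ids_a, ids_b, pt = _null_pair(seed * 100 + rep)
        res = DifferentialDynamics(
            logm.values[ids_a], pt.loc[ids_a].to_numpy(),
            logm.values[ids_b], pt.loc[ids_b].to_numpy(),
        ).fit(seed=rep)
        clean += len(res.affected_genes) == 0
    return {"clean_replicates": clean, "n_reps": n_reps}


def divergence_power(seed: int = 1, n_target: int = 50) -> dict:
    """Sensitivity to a late 2-log2-unit divergence over the last third."""
    logm, ids_a, ids_b, pt = _null_pair(seed)
    span = 22.0
    onset = span * 2.0 / 3.0
    vb = logm.values[ids_b].copy()
    target = list(logm.gene_ids[:n_target])
    lat_b = pt.loc[ids_b].to_numpy()
    ramp = np.clip((lat_b - onset) / (span - onset), 0.0, 1.0) * 2.0
    vb.loc[target] = vb.loc[target].to_numpy() + ramp[None, :]
    res = DifferentialDynamics(
        logm.values[ids_a], pt.loc[ids_a].to_numpy(), vb, lat_b
    ).fit(seed=seed)
    hit = res.table.loc[target]
    sens = float((hit["passes_significance"] & hit["passes_effect"]).mean())
    return {"sensitivity": sens, "n_target": n_target}


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def projection_oracle_error(seed: int = 1) -> dict:
    """Agreement of the segment basis with a direct eigendecomposition, and
    linearity of the projection (centroid midpoint test)."""
    matrix, _ = generate_segment_profiles(
        n_genes=100, gradient_families=(0.4, 0.4, 0.2), n_replicates=6,
        noise_sd=0.2, seed=seed,
    )
    model = fit_segment_basis(matrix)
    X = matrix.values.to_numpy().T
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    score_err = 0.0
    for j in range(2):
        ref = Xc @ evecs[:, j]
        got = model.training_scores[f"PC{j + 1}"].to_numpy()
        sign = np.sign(ref @ got) or 1.0
        score_err = max(score_err, float(np.max(np.abs(got - sign * ref))))

    seg_means = matrix.values.T.groupby(matrix.samples["segment"]).mean().T
    a = seg_means[["head"]].rename(columns={"head": "x"})
    b = seg_means[["foot"]].rename(columns={"foot": "x"})
    mid = (a + b) / 2.0
    sm = model.project(mid).to_numpy()
    expected = (model.project(a).to_numpy() + model.project(b).to_numpy()) / 2.0
    midpoint_err = float(np.max(np.abs(sm - expected)))
    return {"score_error": score_err, "midpoint_error": midpoint_err}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _moods_oracle(a, b):
    pooled = sorted(list(a) + list(b))
    n = len(pooled)
    med = (
        pooled[n // 2]
        if n % 2 == 1
        else (pooled[n // 2 - 1] + pooled[n // 2]) / 2.0
    )
    table = []
    for g in (a, b):
        le = sum(1 for v in g if v <= med)
        table.append([le, len(g) - le])
    table = np.array(table)
    if (table.sum(axis=0) == 0).any():
        return None
    return stats.chi2_contingency(table, correction=True).pvalue


def _wilcoxon_oracle(a, b):
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    p = 2 * min((sums <= w + 1e-9).mean(), (sums >= w - 1e-9).mean())
    return min(1.0, p)


def stats_oracle_error(seed: int = 1, n_cases: int = 200) -> dict:
    """Max |p difference| vs brute-force oracles over small two-group inputs.

    Covers every split (n1, n2) with n1 + n2 <= 8 and values from a small
    integer alphabet, so all tie patterns arise.
    """
    rng = np.random.default_rng(seed)
    max_w = 0.0
    max_m = 0.0
    cases = 0
    while cases < n_cases:
        n1 = int(rng.integers(1, 7))
        n2 = int(rng.integers(1, 9 - n1))
        a = rng.integers(0, 5, n1).astype(float)
        b = rng.integers(0, 5, n2).astype(float)
        w, p = wilcoxon_rank_sum(a, b)
        p_ref = _wilcoxon_oracle(a, b)
        max_w = max(max_w, abs(p - p_ref))
        if np.ptp(np.concatenate([a, b])) > 0:
            ref_m = _moods_oracle(a, b)
            if ref_m is not None:
                try:
                    _, p_m = moods_median_test(a, b)
                    max_m = max(max_m, abs(p_m - ref_m))
                except ValueError:
                    pass
        cases += 1
    return {"wilcoxon_max_abs_diff": max_w, "moods_max_abs_diff": max_m,
            "n_cases": cases}


def stats_alpha_calibration(seed: int = 1, n_reps: int = 1000) -> dict:
    """Null rejection rates of both tests at alpha = 0.05."""
    rng = np.random.default_rng(seed)
    moods_hits = 0
    wil_hits = 0
    for _ in range(n_reps):
        g = [rng.normal(size=50) for _ in range(3)]
        moods_hits += moods_median_test(*g)[1] < 0.05
        wil_hits += wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
    return {
        "moods_alpha": moods_hits / n_reps,
        "wilcoxon_alpha": wil_hits / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segmentation_accuracy(seed: int = 1, radii=(50, 100, 150, 200, 300)) -> dict:
    """Relative radius error on synthetic disks plus the area filter check."""
    errors = {}
    for R in radii:
        size = int(2 * R + 160)
        img = generate_spheroid_image(
            R, int(0.8 * R), image_size=size, noise_sd=0.06, seed=seed
        )
        res = segment_spheroid_image(img, pixel_size=1.3)
        r_px = res.radius_um / 1.3 if res.found else 0.0
        errors[R] = abs(r_px - R) / R
    # a 4000 um^2 object sits below the 5000 um^2 cut and must be excluded
    small = generate_spheroid_image(27.5, 0, image_size=300, noise_sd=0.02,
                                    seed=seed)
    small_found = segment_spheroid_image(small, pixel_size=1.3).found
    return {
        "max_rel_radius_error": float(max(errors.values())),
        "per_radius": {str(k): float(v) for k, v in errors.items()},
        "subthreshold_excluded": not small_found,
    }


# ---------------------------------------------------------------------------
# GAM calibration
# ---------------------------------------------------------------------------

def gam_null_calibration(seed: int = 1, n_reps: int = 200) -> dict:
    """KS uniformity of null smooth-term p-values; power on a clean line."""
    from .gam import fit_gam_many, fit_gam_smooth

    rng = np.random.default_rng(seed)
    t = np.arange(1.0, 51.0)
    Y = rng.normal(size=(50, n_reps))
    p, _, _, _ = fit_gam_many(Y, t, k=10, gamma=1.0)
    ks = stats.kstest(p, "uniform")
    linear = fit_gam_smooth(t.copy(), t, k=10)
    return {
        "ks_pvalue": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "linear_signal_p": float(linear.smooth_p),
        "n_reps": n_reps,
    }
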