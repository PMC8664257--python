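"""Quantification of spheroid inflation/deflation dynamics.

Covers the image-analysis chain (median filter, Phansalkar local threshold,
median filter, hole filling, size filter), cycle extraction from normalized
radius traces (slope, amplitude, period), the phase I -> phase II transition
rule (>= 30% amplitude decrease together with frequency doubling), the
phase-I area under the curve, and the two nonparametric group tests used for
the morphometric comparisons (Mood's median test, Wilcoxon rank-sum).

Rupture happens between frames at ordinary frame rates, so the exact peak
radius is never sampled.  ``detect_cycles`` therefore estimates each cycle's
peak by extrapolating the least-squares fit of the rising limb to the
collapse time; on noise-free sawtooths this recovers slope, amplitude and
period exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, optimize, signal, stats

from .containers import RadiusTrace

__all__ = [
    "Cycle",
    "CycleTable",
    "SegmentationResult",
    "segment_spheroid_image",
    "measure_tissue_thickness",
    "detect_cycles",
    "detect_phase_transition",
    "phase1_area",
    "fit_inflation_slope",
    "moods_median_test",
    "wilcoxon_rank_sum",
]


# ---------------------------------------------------------------------------
# image segmentation
# ---------------------------------------------------------------------------

#: defaults of the segmentation chain (pixels)
MEDIAN_RADIUS_COARSE = 60
THRESHOLD_RADIUS = 50
MEDIAN_RADIUS_FINE = 20
MIN_OBJECT_AREA_UM2 = 5000.0
#: Phansalkar p and q at their standard published values; the r and k terms
#: of the full formula are zeroed, leaving t = m * (1 + p * exp(-q * m)).
PHANSALKAR_P = 2.0
PHANSALKAR_Q = 10.0


@dataclass
class SegmentationResult:
    area_um2: float
    radius_um: float
    mask: np.ndarray
    n_objects: int

    @property
    def found(self) -> bool:
        return self.n_objects > 0

    def __iter__(self):
        # allow ``area, radius, mask = segment_spheroid_image(...)``
        yield self.area_um2
        yield self.radius_um
        yield self.mask


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.uint8)


def _rank_median(img_u8: np.ndarray, radius: int) -> np.ndarray:
    from skimage.filters import rank

    return rank.median(img_u8, footprint=_disk_footprint(radius))


def _local_mean(img: np.ndarray, radius: int) -> np.ndarray:
    """Mean over a circular window, via FFT convolution with edge renorm."""
    from scipy.signal import fftconvolve

    k = _disk_footprint(radius).astype(float)
    num = fftconvolve(img, k, mode="same")
    den = fftconvolve(np.ones_like(img), k, mode="same")
    return num / den


def phansalkar_threshold(
    img: np.ndarray,
    radius: int = THRESHOLD_RADIUS,
    p: float = PHANSALKAR_P,
    q: float = PHANSALKAR_Q,
) -> np.ndarray:
    """Phansalkar local threshold surface for an image scaled to [0, 1].

    The full formula is ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))``; with the
    r and k terms set to zero only the mean-dependent boost remains, which
    makes the threshold sit just above the local mean and pick up faint
    bright structures.
    """
    m = _local_mean(img, radius)
    return m * (1.0 + p * np.exp(-q * m))


# --- curvature bias of binary median filtering -----------------------------

def _disk_window_coverage(R: float, rho: float, d: float) -> float:
    """Fraction of a window of radius rho, centred at distance d from the
    centre of a disk of radius R, that lies inside the disk."""
    if d >= R + rho:
        return 0.0
    if d <= abs(R - rho):
        return min(R, rho) ** 2 / rho**2
    a1 = R**2 * np.arccos((d**2 + R**2 - rho**2) / (2 * d * R))
    a2 = rho**2 * np.arccos((d**2 + rho**2 - R**2) / (2 * d * rho))
    a3 = 0.5 * np.sqrt(
        (-d + R + rho) * (d + R - rho) * (d - R + rho) * (d + R + rho)
    )
    return (a1 + a2 - a3) / (np.pi * rho**2)


def _median_eroded_radius(R: float, rho: float) -> float:
    """Radius of a binary disk after a median filter with window radius rho.

    The output of a median filter on a binary disk is dark exactly where the
    window is at least half covered, so the boundary moves inward to the
    50%-coverage locus; small disks vanish entirely (returned as 0).
    """
    if R <= 0:
        return 0.0
    f = lambda d: _disk_window_coverage(R, rho, d) - 0.5
    if f(0.0) < 0:
        return 0.0
    return float(optimize.brentq(f, 1e-9, R + rho))


def _chain_response(R: float) -> float:
    """Apparent disk radius after the coarse and fine median filters."""
    return _median_eroded_radius(
        _median_eroded_radius(R, MEDIAN_RADIUS_COARSE), MEDIAN_RADIUS_FINE
    )


def correct_curvature_bias(radius_px: float) -> float:
    """Invert the median-filter erosion model for a circular object.

    Median filtering erodes convex boundaries by a curvature-dependent
    offset.  For a spherical object (the working assumption of the whole
    radius readout) the erosion of the two median stages is known in closed
    geometric form, so the true radius can be recovered by inverting the
    composed response.
    """
    if radius_px <= 0:
        return radius_px
    g = lambda R: _chain_response(R) - radius_px
    lo, hi = radius_px, radius_px + MEDIAN_RADIUS_COARSE + MEDIAN_RADIUS_FINE + 5.0
    if g(lo) > 0:  # response never shrinks below identity on this branch
        return radius_px
    return float(optimize.brentq(g, lo, hi))


def segment_spheroid_image(
    image: np.ndarray,
    pixel_size: float = 1.3,
    min_area_um2: float = MIN_OBJECT_AREA_UM2,
    curvature_correction: bool = True,
) -> SegmentationResult:
    """Segment a dark spheroid on a bright background and measure its size.

    Chain: coarse median filter (radius 60 px), Phansalkar local threshold
    (window radius 50 px, r and k terms zeroed), fine median filter (radius
    20 px), hole filling, then the area of connected components larger than
    ``min_area_um2`` (holes included).  The radius assumes a spherical
    object: ``r = sqrt(area / pi)``.  ``curvature_correction`` additionally
    inverts the known erosion of median filtering on circular boundaries,
    which otherwise biases the radius low (strongly so for small objects).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    img = image.astype(float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    # the object is dark on a bright background; work on the inverted image
    inv = 1.0 - img
    inv_u8 = np.round(inv * 255).astype(np.uint8)

    smoothed = _rank_median(inv_u8, MEDIAN_RADIUS_COARSE).astype(float) / 255.0
    fg = smoothed > phansalkar_threshold(smoothed)
    fg = _rank_median((fg * 255).astype(np.uint8), MEDIAN_RADIUS_FINE) > 127
    fg = ndimage.binary_fill_holes(fg)

    labels, n = ndimage.label(fg)
    if n == 0:
        return SegmentationResult(0.0, 0.0, np.zeros_like(fg), 0)
    sizes_px = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    areas_um2 = sizes_px * pixel_size**2
    keep = np.flatnonzero(areas_um2 > min_area_um2) + 1
    if keep.size == 0:
        return SegmentationResult(0.0, 0.0, np.zeros_like(fg), 0)
    mask = np.isin(labels, keep)
    area_um2 = float(mask.sum() * pixel_size**2)
    radius_px = np.sqrt(mask.sum() / np.pi)
    if curvature_correction:
        radius_px = correct_curvature_bias(radius_px)
        area_um2 = float(np.pi * radius_px**2 * pixel_size**2)
    return SegmentationResult(area_um2, radius_px * pixel_size, mask, int(keep.size))


def measure_tissue_thickness(image: np.ndarray, pixel_size: float = 1.0) -> float:
    """Average tissue thickness from an equatorial fluorescence section.

    Segments the whole optical section (tissue ring with its interior) and
    the lumen cavity, converts both areas to equivalent-disk radii and
    returns their difference: ``sqrt(A_out/pi) - sqrt(A_in/pi)``.
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    # two passes of light 3x3 smoothing, then a global threshold
    for _ in range(2):
        image = ndimage.uniform_filter(image, size=3)
    if image.max() <= image.min():
        raise ValueError("blank image: no tissue ring found")
    def ring_and_cavity(threshold):
        tissue = image > threshold
        if not tissue.any():
            return None
        labels, n = ndimage.label(tissue)
        if n > 1:
            sizes = ndimage.sum_labels(
                np.ones_like(labels), labels, np.arange(1, n + 1)
            )
            tissue = labels == (int(np.argmax(sizes)) + 1)
        whole = ndimage.binary_fill_holes(tissue)
        lumen = whole & ~tissue
        if lumen.sum() == 0:
            return None
        return whole, lumen

    result = ring_and_cavity(threshold_otsu(image))
    if result is None:
        # a lumen brighter than background merges with the ring under a
        # single global threshold; separate three intensity classes instead
        from skimage.filters import threshold_multiotsu

        try:
            thresholds = threshold_multiotsu(image, classes=3)
            result = ring_and_cavity(thresholds[-1])
        except ValueError:
            result = None
    if result is None:
        raise ValueError("no lumen: the section has no enclosed cavity")
    whole, lumen = result
    lab_l, n_l = ndimage.label(lumen)
    sizes_l = ndimage.sum_labels(np.ones_like(lab_l), lab_l, np.arange(1, n_l + 1))
    a_in = float(np.max(sizes_l))
    a_out = float(whole.sum())
    if a_in >= a_out:
        raise ValueError("lumen area is not smaller than the section area")
    return (np.sqrt(a_out / np.pi) - np.sqrt(a_in / np.pi)) * pixel_size


# ---------------------------------------------------------------------------
# cycle extraction
# ---------------------------------------------------------------------------

@dataclass
class Cycle:
    """One inflation/deflation cycle: trough -> peak -> post-collapse trough."""

    start_index: int
    peak_index: int
    end_index: int
    slope: float  # normalized radius per hour (least squares, rising limb)
    amplitude: float  # extrapolated peak minus preceding trough
    period: float  # hours between consecutive troughs

    def __post_init__(self):
        if not (self.start_index < self.peak_index <= self.end_index):
            raise ValueError("cycle indices must satisfy start < peak <= end")


@dataclass
class CycleTable:
    cycles: list[Cycle] = field(default_factory=list)
    transition_index: int | None = None  # 1-based ordinal of first phase-II cycle
    phase1_area: float | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.cycles])

    @property
    def periods(self) -> np.ndarray:
        return np.array([c.period for c in self.cycles])

    @property
    def slopes(self) -> np.ndarray:
        return np.array([c.slope for c in self.cycles])

    def to_frame(self):
        import pandas as pd

        phase = []
        for i in range(len(self.cycles)):
            if self.transition_index is not None and i + 1 >= self.transition_index:
                phase.append("II")
            else:
                phase.append("I")
        return pd.DataFrame(
            {
                "cycle_ordinal": np.arange(1, len(self.cycles) + 1),
                "slope": self.slopes,
                "amplitude": self.amplitudes,
                "period": self.periods,
                "phase": phase,
            }
        )


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tm, ym = t.mean(), y.mean()
    dt = t - tm
    denom = np.sum(dt * dt)
    if denom == 0:
        return 0.0, ym
    slope = np.sum(dt * (y - ym)) / denom
    return slope, ym - slope * tm


def detect_cycles(
    trace: RadiusTrace,
    min_amplitude: float = 0.1,
    min_drop_fraction: float = 0.3,
    drop_window: int = 3,
) -> CycleTable:
    """Extract inflation/deflation cycles from a normalized radius trace.

    A rupture is a decrease of at least ``min_drop_fraction`` of the running
    peak-to-trough span occurring within ``drop_window`` frames of the
    running peak.  Each cycle spans trough -> peak -> post-collapse trough;
    its slope is the least-squares fit over the rising limb, its amplitude
    the rising-limb fit extrapolated to the collapse time minus the starting
    trough (the true peak falls between frames), and its period the time
    between consecutive troughs.  Cycles with amplitude below
    ``min_amplitude`` are discarded.  Flat or monotone traces simply yield
    no cycles.
    """
    r, t = trace.radius, trace.time
    n = len(r)
    raw: list[tuple[int, int, int]] = []
    s = 0
    m, mi = r[0], 0  # running cycle maximum
    i = 1
    while i < n:
        if r[i] > m:
            m, mi = r[i], i
        span = m - r[s]
        recent_max = np.max(r[max(s, i - drop_window) : i])
        drop = recent_max - r[i]
        if (
            span >= min_amplitude
            and drop >= max(min_drop_fraction * span, min_amplitude)
            and mi > s
        ):
            # extend to the local minimum of the collapse
            end = i
            while end + 1 < n and r[end + 1] < r[end] and end - i < drop_window:
                end += 1
            raw.append((s, mi, end))
            s = end
            m, mi = r[end], end
            i = end + 1
            continue
        i += 1

    cycles = []
    for (cs, cp, ce) in raw:
        slope, intercept = _ols_line(t[cs : cp + 1], r[cs : cp + 1])
        peak_est = intercept + slope * t[ce]
        amplitude = peak_est - r[cs]
        period = t[ce] - t[cs]
        if amplitude >= min_amplitude and period > 0 and cp > cs:
            cycles.append(Cycle(cs, cp, ce, slope, amplitude, period))
    return CycleTable(cycles=cycles)


def detect_phase_transition(table: CycleTable) -> int | None:
    """First cycle satisfying the phase I -> II criterion, as 1-based ordinal.

    A cycle marks the transition when its amplitude has dropped by at least
    30% relative to the median amplitude of all preceding cycles AND its
    period is at most half the median preceding period (frequency doubling).
    Returns ``None`` when the criterion is never met or fewer than two
    cycles exist.
    """
    cycles = table.cycles
    if len(cycles) < 2:
        return None
    amps = [c.amplitude for c in cycles]
    pers = [c.period for c in cycles]
    for j in range(1, len(cycles)):
        amp_med = float(np.median(amps[:j]))
        per_med = float(np.median(pers[:j]))
        if amps[j] <= 0.7 * amp_med and pers[j] <= 0.5 * per_med:
            table.transition_index = j + 1
            return j + 1
    table.transition_index = None
    return None


def _integral_above(times: np.ndarray, values: np.ndarray, baseline: float) -> float:
    """Exact integral of max(v - baseline, 0) over a piecewise-linear curve."""
    total = 0.0
    v = np.asarray(values, dtype=float) - baseline
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        v0, v1 = v[i], v[i + 1]
        if t1 <= t0:
            continue
        if v0 <= 0 and v1 <= 0:
            continue
        if v0 >= 0 and v1 >= 0:
            total += 0.5 * (v0 + v1) * (t1 - t0)
        else:
            # segment crosses the baseline once
            tc = t0 + (t1 - t0) * (0.0 - v0) / (v1 - v0)
            if v0 > 0:
                total += 0.5 * v0 * (tc - t0)
            else:
                total += 0.5 * v1 * (t1 - tc)
    return total


def phase1_area(trace: RadiusTrace, table: CycleTable) -> float:
    """Area under the phase-I part of the trace, above the initial radius.

    Integrates ``max(radius - 1, 0)`` from the trace start to the end of the
    last phase-I cycle (the whole trace when no transition was found).  At
    each detected collapse the unobserved rupture peak is reconstructed from
    the rising-limb fit so the sawtooth's triangular geometry integrates
    exactly.
    """
    r, t = trace.radius, trace.time
    if table.transition_index is not None and table.transition_index >= 2:
        last = table.cycles[table.transition_index - 2]
        stop = last.end_index
        phase1_cycles = table.cycles[: table.transition_index - 1]
    else:
        stop = len(r) - 1
        phase1_cycles = table.cycles

    times, values = [], []
    peak_at_end = {c.end_index: r[c.start_index] + c.amplitude for c in phase1_cycles}
    for i in range(stop + 1):
        if i in peak_at_end:
            times.append(t[i])
            values.append(peak_at_end[i])
        times.append(t[i])
        values.append(r[i])
    area = _integral_above(np.asarray(times), np.asarray(values), baseline=1.0)
    table.phase1_area = area
    return area


# ---------------------------------------------------------------------------
# simple statistics
# ---------------------------------------------------------------------------

def fit_inflation_slope(x, y, conf_level: float = 0.95):
    """Ordinary least squares slope with a confidence interval.

    Used for rate-vs-rate comparisons such as spheroid inflation slope
    against the slope of Wnt3 expression.  Returns
    ``(slope, intercept, (ci_low, ci_high))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
    half = tcrit * res.stderr
    return res.slope, res.intercept, (res.slope - half, res.slope + half)


def moods_median_test(*groups):
    """Mood's median test for two or more groups (two-sided).

    Dichotomizes all values at the grand median, builds the
    group x {<= median, > median} contingency table and applies Pearson's
    chi-square (Yates continuity correction only in the 2x2 case).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; the median test is undefined")
    med = np.median(pooled)
    table = np.array([[np.sum(g <= med), np.sum(g > med)] for g in groups])
    if (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate dichotomy: one side of the median is empty")
    correction = len(groups) == 2
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w: float) -> float:
    n = len(ranks)
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks, n1)), dtype=float
    )
    tol = 1e-9
    p_le = np.mean(sums <= w + tol)
    p_ge = np.mean(sums >= w - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(a, b, exact_limit: int = 20):
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    Exact permutation distribution of the rank sum for small samples
    (total n <= ``exact_limit``); otherwise a tie-corrected normal
    approximation with continuity correction.  Returns ``(W, p)`` with W the
    rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    w = float(np.sum(ranks[:n1]))
    if n <= exact_limit:
        return w, _exact_rank_sum_p(ranks, n1, w)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
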