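"""Differential gene-expression dynamics between media conditions.

Two pseudotime-ordered expression series (e.g. plain medium vs isotonic
70 mM sucrose) are interpolated onto a common 150-point grid; the per-gene
difference signal is standardized and tested with a GAM smooth (k = 8),
while an effect size — the summed absolute difference of the mean-centred
signals, excluding the first three grid points — captures scale changes the
shape test is blind to.  Genes passing both the FDR cut (1e-6) and the
effect cut (40) count as mechanosensitive; within the significant pool the
top 10% by effect size are flagged.  Changing genes are k-means clustered
(k = 5) on their mean-centred profiles.  Intron/exon trajectory smoothing
and ddCt-based relative qPCR quantification round out the module.

Statsmodels-style entry point: ``DifferentialDynamics(...).fit()`` returns a
``DifferentialResults`` with the per-gene table and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .gam import SplineBasis, benjamini_hochberg, fit_gam_many
from .preprocessing import moving_average

__all__ = [
    "AlignedSeriesPair",
    "align_series",
    "delta_gam_test",
    "effect_size",
    "select_affected_genes",
    "cluster_profiles",
    "intron_exon_trajectory",
    "relative_expression_ddct",
    "DifferentialDynamics",
    "DifferentialResults",
]

DEFAULT_N_POINTS = 150
DEFAULT_P_CUT = 1e-6
DEFAULT_EFFECT_CUT = 40.0
DEFAULT_TOP_FRACTION = 0.10


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedSeriesPair:
    """Two per-gene series interpolated to one pseudotime grid.

    ``interp_cov`` is the covariance structure the linear interpolation
    induces on the delta signal under independent, homoskedastic per-sample
    noise: ``V = L_A L_A' + L_B L_B'`` with L the interpolation weight
    matrices.  The delta smooth test whitens with it, which keeps the test
    calibrated despite the serial correlation interpolation creates.
    """

    grid: np.ndarray
    series_a: pd.DataFrame  # genes x grid points
    series_b: pd.DataFrame
    interp_cov: np.ndarray | None = None

    def __post_init__(self):
        if self.series_a.shape != self.series_b.shape:
            raise ValueError("interpolated series must have equal shapes")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def delta(self) -> pd.DataFrame:
        return self.series_b - self.series_a

    @property
    def n_points(self) -> int:
        return len(self.grid)


def _interp_operator(t_sorted: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear-interpolation weight matrix: grid points x sorted samples."""
    n, m = len(grid), len(t_sorted)
    L = np.zeros((n, m))
    idx = np.clip(np.searchsorted(t_sorted, grid, side="right") - 1, 0, m - 2)
    left, right = t_sorted[idx], t_sorted[idx + 1]
    width = np.where(right > left, right - left, 1.0)
    alpha = np.clip((grid - left) / width, 0.0, 1.0)
    rows = np.arange(n)
    L[rows, idx] += 1.0 - alpha
    L[rows, idx + 1] += alpha
    return L


def _interp_matrix(
    values: pd.DataFrame, t: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(t, kind="mergesort")
    ts = t[order]
    vs = values.to_numpy(dtype=float)[:, order]
    L = _interp_operator(ts, grid)
    return vs @ L.T, L


def align_series(
    series_a: pd.DataFrame,
    pseudotime_a: np.ndarray,
    series_b: pd.DataFrame,
    pseudotime_b: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
) -> AlignedSeriesPair:
    """Interpolate both conditions to ``n_points`` shared pseudotimes.

    The grid spans the intersection of the two pseudotime ranges, so no
    value is extrapolated.  Within the range, each gene is interpolated
    linearly between its samples.
    """
    pa = np.asarray(pseudotime_a, dtype=float)
    pb = np.asarray(pseudotime_b, dtype=float)
    if series_a.shape[1] != len(pa) or series_b.shape[1] != len(pb):
        raise ValueError("pseudotime length must match the sample count")
    if series_a.shape[1] < 2 or series_b.shape[1] < 2:
        raise ValueError("need at least two samples per condition")
    lo = max(pa.min(), pb.min())
    hi = min(pa.max(), pb.max())
    if hi <= lo:
        raise ValueError("pseudotime ranges do not overlap")
    genes = series_a.index
    if not genes.equals(series_b.index):
        shared = genes.intersection(series_b.index)
        if len(shared) == 0:
            raise ValueError("no shared genes")
        series_a, series_b = series_a.loc[shared], series_b.loc[shared]
        genes = shared
    grid = np.linspace(lo, hi, n_points)
    A, La = _interp_matrix(series_a, pa, grid)
    B, Lb = _interp_matrix(series_b, pb, grid)
    cols = [f"t{i:03d}" for i in range(n_points)]
    V = La @ La.T + Lb @ Lb.T
    return AlignedSeriesPair(
        grid,
        pd.DataFrame(A, index=genes, columns=cols),
        pd.DataFrame(B, index=genes, columns=cols),
        interp_cov=V,
    )


# ---------------------------------------------------------------------------
# testing and effect sizes
# ---------------------------------------------------------------------------

def _whitened_smooth_pvalues(
    Z: np.ndarray, grid: np.ndarray, V: np.ndarray, k: int
) -> np.ndarray:
    """Exact F test of spline-vs-constant after whitening with V.

    ``Z`` is grid points x genes.  The delta signal inherits the known
    covariance ``sigma^2 V`` from linear interpolation of independent
    sample noise; transforming into the eigenspace of V (dropping
    near-null directions) restores an i.i.d. error model in which the
    F test is exact.
    """
    from scipy import stats as sps

    evals, Q = np.linalg.eigh(V)
    keep = evals > 1e-10 * evals.max()
    Q, evals = Q[:, keep], evals[keep]
    W = Q / np.sqrt(evals)  # grid x m; W' z whitens
    Zw = W.T @ Z  # m x genes
    X = SplineBasis(grid, k).X
    Xw = W.T @ X
    cw = W.T @ np.ones(len(grid))  # whitened constant regressor
    m = Zw.shape[0]

    beta1, *_ = np.linalg.lstsq(Xw, Zw, rcond=None)
    rss1 = np.sum((Zw - Xw @ beta1) ** 2, axis=0)
    rank1 = np.linalg.matrix_rank(Xw)
    beta0 = (cw @ Zw) / (cw @ cw)
    rss0 = np.sum((Zw - np.outer(cw, beta0)) ** 2, axis=0)
    df1, df2 = rank1 - 1, m - rank1
    if df2 <= 0:
        raise ValueError("interpolation covariance leaves too few directions")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return np.where(rss1 <= 0, 0.0, sps.f.sf(F, df1, df2))


def delta_gam_test(
    pair: AlignedSeriesPair, k: int = 8, gamma: float = 1.0
) -> pd.DataFrame:
    """GAM smooth test of the standardized per-gene difference signal.

    Each gene's delta is scaled to unit variance and fitted against the
    grid with a spline smooth of basis dimension ``k`` (GCV-penalized fit
    supplies the effective degrees of freedom).  The smooth-term p-value
    whitens the interpolation-induced correlation when the pair carries the
    operator covariance; p-values are BH-adjusted across genes.  Genes
    whose delta has zero variance get p = 1 and are flagged.
    """
    delta = pair.delta.to_numpy(dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta contains non-finite values")
    sd = delta.std(axis=1, ddof=0)
    flat = sd <= 0
    sd_safe = np.where(flat, 1.0, sd)
    Z = (delta / sd_safe[:, None]).T  # grid points x genes
    p, edf, _, _ = fit_gam_many(Z, pair.grid, k=k, gamma=gamma)
    if pair.interp_cov is not None:
        p = _whitened_smooth_pvalues(Z, pair.grid, pair.interp_cov, k)
    p = np.where(flat, 1.0, p)
    return pd.DataFrame(
        {
            "smooth_p": p,
            "p_adjusted": benjamini_hochberg(p),
            "edf": edf,
            "zero_variance": flat,
        },
        index=pair.series_a.index,
    )


def effect_size(pair: AlignedSeriesPair, exclude_first: int = 3) -> pd.Series:
    """Summed absolute difference of the mean-centred signals.

    Both conditions are centred by their own mean (making the measure
    invariant to condition-wide offsets), then the absolute differences are
    summed over the grid, excluding the first ``exclude_first`` highly
    variable points.
    """
    if pair.n_points <= exclude_first:
        raise ValueError("grid shorter than the excluded prefix")
    A = pair.series_a.to_numpy(dtype=float)
    B = pair.series_b.to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    eff = np.abs(Ac - Bc)[:, exclude_first:].sum(axis=1)
    return pd.Series(eff, index=pair.series_a.index, name="effect_size")


def select_affected_genes(
    table: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    effect_cut: float = DEFAULT_EFFECT_CUT,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> pd.DataFrame:
    """Set significance/effect flags and mark the top fraction by effect.

    ``passes_significance``: FDR-adjusted p below ``p_cut``;
    ``passes_effect``: effect size above ``effect_cut``; ``top_flag``: the
    top ``top_fraction`` of the significant pool ranked by effect size
    (ties broken by gene id for determinism).
    """
    out = table.copy()
    out["passes_significance"] = out["p_adjusted"] < p_cut
    out["passes_effect"] = out["effect_size"] > effect_cut
    out["top_flag"] = False
    pool = out.index[out["passes_significance"]]
    if len(pool):
        n_top = max(1, int(round(top_fraction * len(pool))))
        ranked = (
            out.loc[pool]
            .assign(_gid=pool.astype(str))
            .sort_values(["effect_size", "_gid"], ascending=[False, True])
        )
        out.loc[ranked.index[:n_top], "top_flag"] = True
    return out


# ---------------------------------------------------------------------------
# clustering and trajectory shape
# ---------------------------------------------------------------------------

def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 5,
    n_restarts: int = 25,
    seed: int = 0,
    mean_normalize: bool = True,
) -> pd.Series:
    """k-means clustering of (mean-centred) expression time series.

    ``profiles`` is genes x grid points, typically restricted to genes
    changing at least twofold over the course.  The best of ``n_restarts``
    k-means++ initializations is kept; fixed ``seed`` gives a deterministic
    assignment.  Cluster ids are 1..k, relabelled by decreasing cluster
    size for stability.
    """
    if len(profiles) < k:
        raise ValueError("fewer genes than clusters")
    X = profiles.to_numpy(dtype=float)
    if mean_normalize:
        X = X - X.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    return pd.Series([remap[l] for l in labels], index=profiles.index,
                     name="cluster_id")


def intron_exon_trajectory(
    intronic: np.ndarray | pd.Series,
    exonic: np.ndarray | pd.Series,
    window: int = 36,
    baseline_percentile: float = 10.0,
) -> pd.DataFrame:
    """Smoothed paired intron/exon trajectory with a phase classification.

    Both pseudotime-ordered series are smoothed with a centred moving
    average (window 36 points).  Each point is classified:
    ``transcription`` when the smoothed intronic signal is above the
    midpoint between its baseline (the ``baseline_percentile`` quantile)
    and its upper level, or while the intronic signal is still rising;
    ``degradation`` when the intronic signal sits at baseline while the
    exonic signal falls (mRNA decay outlasting transcription);
    ``quiescent`` otherwise.
    """
    intr = np.asarray(intronic, dtype=float)
    exon = np.asarray(exonic, dtype=float)
    if intr.shape != exon.shape:
        raise ValueError("intronic and exonic series must have equal length")
    intr_s = moving_average(intr, window)
    exon_s = moving_average(exon, window)

    lo = np.percentile(intr_s, baseline_percentile)
    hi = np.percentile(intr_s, 100.0 - baseline_percentile)
    dynamic_range = hi - lo
    scale = max(abs(hi), abs(lo), 1e-12)
    has_transcription_phase = dynamic_range > 1e-6 * scale
    thr = lo + 0.5 * dynamic_range

    d_intr = np.gradient(intr_s)
    d_exon = np.gradient(exon_s)
    eps = 1e-8 * max(np.abs(exon_s).max(), np.abs(intr_s).max(), 1e-12)

    phase = np.full(len(intr_s), "quiescent", dtype=object)
    if has_transcription_phase:
        phase[intr_s >= thr] = "transcription"
        phase[(phase == "quiescent") & (d_intr > eps)] = "transcription"
    falling = d_exon < -eps
    phase[(phase == "quiescent") & falling] = "degradation"
    return pd.DataFrame(
        {
            "intronic_smooth": intr_s,
            "exonic_smooth": exon_s,
            "phase": phase,
        }
    )


def transcription_shutoff_point(trajectory: pd.DataFrame) -> int | None:
    """Grid index where the smoothed intronic signal drops through the
    midpoint of its dynamic range after its maximum (transcription off)."""
    intr = trajectory["intronic_smooth"].to_numpy()
    lo, hi = np.percentile(intr, [10, 90])
    if hi - lo <= 1e-6 * max(abs(hi), abs(lo), 1e-12):
        return None
    thr = lo + 0.5 * (hi - lo)
    peak = int(np.argmax(intr))
    below = np.flatnonzero(intr[peak:] < thr)
    if len(below) == 0:
        return None
    return int(peak + below[0])


# ---------------------------------------------------------------------------
# qPCR quantification
# ---------------------------------------------------------------------------

def relative_expression_ddct(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    calibrator_sample: str,
) -> pd.Series:
    """Relative expression by the 2^-ddCt method.

    ``dCt = Ct(target) - Ct(reference)`` per sample; ``ddCt`` is taken
    relative to the calibrator sample (e.g. the initial time point of each
    condition); the returned fold change is ``2 ** -ddCt``.
    """
    ct_target = pd.Series(ct_target, dtype=float)
    ct_reference = pd.Series(ct_reference, dtype=float).reindex(ct_target.index)
    if ct_reference.isna().any():
        missing = list(ct_target.index[ct_reference.isna()])
        raise ValueError(f"missing reference Ct for samples: {missing}")
    if calibrator_sample not in ct_target.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not found")
    dct = ct_target - ct_reference
    ddct = dct - dct.loc[calibrator_sample]
    return pd.Series(2.0 ** (-ddct), index=ct_target.index, name="fold_change")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialDynamics:
    """Condition-comparison model for pseudotime-ordered expression.

    Parameters
    ----------
    series_a, series_b
        Genes x samples log2 matrices of the two conditions, with matching
        gene sets (intersected otherwise).
    pseudotime_a, pseudotime_b
        Per-sample pseudotime of each condition.
    n_points, k, gamma, exclude_first, p_cut, effect_cut, top_fraction
        Grid size and test/selection parameters (defaults as in the study:
        150 points, k=8, FDR < 1e-6, effect > 40, top 10%).
    """

    def __init__(
        self,
        series_a: pd.DataFrame,
        pseudotime_a: np.ndarray,
        series_b: pd.DataFrame,
        pseudotime_b: np.ndarray,
        n_points: int = DEFAULT_N_POINTS,
        k: int = 8,
        gamma: float = 1.0,
        exclude_first: int = 3,
        p_cut: float = DEFAULT_P_CUT,
        effect_cut: float = DEFAULT_EFFECT_CUT,
        top_fraction: float = DEFAULT_TOP_FRACTION,
        n_clusters: int = 5,
        min_change_log2: float = 1.0,
    ):
        self.series_a = series_a
        self.series_b = series_b
        self.pseudotime_a = np.asarray(pseudotime_a, dtype=float)
        self.pseudotime_b = np.asarray(pseudotime_b, dtype=float)
        self.n_points = n_points
        self.k = k
        self.gamma = gamma
        self.exclude_first = exclude_first
        self.p_cut = p_cut
        self.effect_cut = effect_cut
        self.top_fraction = top_fraction
        self.n_clusters = n_clusters
        self.min_change_log2 = min_change_log2

    def fit(self, seed: int = 0) -> "DifferentialResults":
        pair = align_series(
            self.series_a, self.pseudotime_a,
            self.series_b, self.pseudotime_b, self.n_points,
        )
        table = delta_gam_test(pair, k=self.k, gamma=self.gamma)
        table["effect_size"] = effect_size(pair, self.exclude_first)
        table = select_affected_genes(
            table, self.p_cut, self.effect_cut, self.top_fraction
        )
        # direction: does the gene rise or fall over the course (condition A)?
        A = pair.series_a.to_numpy(dtype=float)
        third = max(1, pair.n_points // 3)
        table["direction"] = np.where(
            A[:, -third:].mean(axis=1) >= A[:, :third].mean(axis=1),
            "increasing",
            "decreasing",
        )
        # cluster genes changing at least twofold along the reference course
        changing = pair.series_a.index[
            (A.max(axis=1) - A.min(axis=1)) >= self.min_change_log2
        ]
        table["cluster_id"] = pd.NA
        if len(changing) >= self.n_clusters:
            clusters = cluster_profiles(
                pair.series_a.loc[changing], k=self.n_clusters, seed=seed
            )
            table.loc[changing, "cluster_id"] = clusters
        return DifferentialResults(self, pair, table)


@dataclass
class DifferentialResults:
    model: DifferentialDynamics
    pair: AlignedSeriesPair
    table: pd.DataFrame

    @property
    def affected_genes(self) -> pd.Index:
        m = self.table["passes_significance"] & self.table["passes_effect"]
        return self.table.index[m]

    @property
    def top_genes(self) -> pd.Index:
        return self.table.index[self.table["top_flag"]]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Differential expression dynamics",
            "================================",
            f"genes tested:             {len(t)}",
            f"grid points:              {self.pair.n_points}",
            f"FDR < {self.model.p_cut:g}:              {int(t['passes_significance'].sum())}",
            f"effect > {self.model.effect_cut:g}:              {int(t['passes_effect'].sum())}",
            f"significant & effect:     {len(self.affected_genes)}",
            f"top {self.model.top_fraction:.0%} flagged:          {len(self.top_genes)}",
            f"genes clustered (>=2x):   {int(t['cluster_id'].notna().sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
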