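"""Pseudotime ordering of asynchronously developing spheroid samples.

Samples collected at the same clock hour sit at different points of the
developmental program.  The ordering strategy: (1) keep the top 50% most
variable genes by a mean-variance trend fit; (2) keep only the principal
components whose scores vary smoothly with collection time (GAM smooth-term
FDR < alpha) and reconstruct the matrix from them, removing variation
orthogonal to the dynamics; (3) slide 7-hour windows along the collection
grid, select the genes with a significant smooth time trend inside each
window, and run an ensemble of one-dimensional isomap embeddings on random
half-subsets of those genes; (4) average the per-window coordinates into a
consensus pseudotime, weighting each window by the number and significance
of its selected genes.

Exposed in statsmodels style: ``PseudotimeModel(matrix).fit(seed)`` returns a
``PseudotimeResults`` with the consensus table, per-window estimates and
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .containers import ExpressionMatrix
from .gam import NEGLOG10_P_CAP, SplineBasis, benjamini_hochberg, fit_gam_many

__all__ = [
    "PseudotimeModel",
    "PseudotimeResults",
    "WindowEstimate",
    "select_variable_genes",
    "denoise_by_time_components",
    "window_gene_selection",
    "ensemble_embedding",
    "consensus_pseudotime",
    "median_collection_spread",
]


# ---------------------------------------------------------------------------
# feature selection and denoising
# ---------------------------------------------------------------------------

def select_variable_genes(matrix: ExpressionMatrix, fraction: float = 0.5) -> list[str]:
    """Top ``fraction`` most variable genes against a mean-variance trend.

    A quadratic smooth of log-variance on log-mean across genes supplies the
    expected variance at each expression level; genes are ranked by their
    residual above the trend.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if matrix.n_genes < 10:
        raise ValueError("need at least 10 genes for a mean-variance trend")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    lm = np.log10(np.maximum(mean - mean.min() + 1e-9, 1e-9))
    lv = np.log10(np.maximum(var, 1e-12))
    coef = np.polyfit(lm, lv, deg=2)
    resid = lv - np.polyval(coef, lm)
    n_keep = max(1, int(round(fraction * matrix.n_genes)))
    order = np.argsort(-resid, kind="mergesort")
    return list(matrix.gene_ids[order[:n_keep]])


def denoise_by_time_components(
    matrix: ExpressionMatrix,
    t: pd.Series | np.ndarray | None = None,
    n_components: int = 50,
    alpha: float = 0.05,
    k: int = 10,
    gamma: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Reconstruct the matrix from time-associated principal components.

    Each of the first ``n_components`` PC score vectors is fitted against
    collection time with a GAM smooth; components whose FDR-adjusted
    smooth-term p-value is below ``alpha`` are kept and the matrix is rebuilt
    from them (gene means restored).  Raises when no component carries a
    time signal.
    """
    if t is None:
        t = matrix.samples["collection_time"]
    t = np.asarray(t, dtype=float)
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    n_comp = min(n_components, min(Xc.shape) - 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_comp] * s[:n_comp]

    p, edf, _, _ = fit_gam_many(scores, t, k=min(k, len(np.unique(t))), gamma=gamma)
    p_adj = benjamini_hochberg(p)
    keep = p_adj < alpha
    report = pd.DataFrame(
        {
            "component": np.arange(1, n_comp + 1),
            "smooth_p": p,
            "p_adjusted": p_adj,
            "edf": edf,
            "kept": keep,
            "variance_fraction": (s[:n_comp] ** 2) / np.sum(s**2),
        }
    )
    if not keep.any():
        raise ValueError(
            "no time-associated components: the matrix carries no time signal"
        )
    recon = scores[:, keep] @ Vt[:n_comp][keep] + center
    out = matrix.copy()
    out.values = pd.DataFrame(
        recon.T, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    return out, report


# ---------------------------------------------------------------------------
# windowed estimation
# ---------------------------------------------------------------------------

@dataclass
class WindowEstimate:
    """Per-window 1-D embedding result for the samples it covers."""

    window_start: float
    window_span: float
    sample_ids: list[str]
    coordinates: np.ndarray  # within [0, window_span]
    weight: float
    selected_genes: pd.Series  # p_adjusted indexed by gene

    @property
    def pseudotimes(self) -> np.ndarray:
        return self.window_start + self.coordinates


def window_gene_selection(
    matrix: ExpressionMatrix,
    t: np.ndarray,
    window: tuple[float, float],
    k: int = 4,
    gamma: float = 1.25,
    alpha: float = 0.05,
    min_samples: int = 8,
) -> pd.Series | None:
    """Genes with a significant smooth time trend inside one window.

    Returns FDR-adjusted p-values for the passing genes, or ``None`` (with a
    warning) when fewer than ``min_samples`` samples fall inside the window.
    Windows are half-open ``[start, stop)`` so that a 22-hour course covered
    by 16 seven-hour windows yields between 1 and 7 windows per sample.
    """
    lo, hi = window
    in_win = (t >= lo) & (t < hi)
    if in_win.sum() < min_samples:
        warnings.warn(
            f"window [{lo}, {hi}) has {int(in_win.sum())} samples; skipped",
            stacklevel=2,
        )
        return None
    tw = t[in_win]
    if len(np.unique(tw)) < 3:
        warnings.warn(
            f"window [{lo}, {hi}) has too few distinct time points; skipped",
            stacklevel=2,
        )
        return None
    Y = matrix.values.to_numpy(dtype=float)[:, in_win].T  # samples x genes
    k_eff = min(k, len(np.unique(tw)))
    if len(tw) < k_eff + 2:
        warnings.warn(f"window [{lo}, {hi}) under-populated; skipped", stacklevel=2)
        return None
    p, _, _, _ = fit_gam_many(Y, tw, k=k_eff, gamma=gamma)
    p_adj = benjamini_hochberg(p)
    sel = p_adj < alpha
    return pd.Series(p_adj[sel], index=matrix.gene_ids[sel], name="p_adjusted")


def _connected_n_neighbors(X: np.ndarray, start: int) -> int:
    """Smallest neighbour count >= start giving a connected kNN graph."""
    n = X.shape[0]
    nn = min(start, n - 1)
    while nn < n:
        graph = kneighbors_graph(X, n_neighbors=nn, include_self=False)
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp == 1:
            return nn
        nn += 1
    raise ValueError("neighborhood graph disconnected even at n - 1 neighbours")


def ensemble_embedding(
    submatrix: pd.DataFrame,
    t: np.ndarray,
    n_iterations: int = 100,
    subset_fraction: float = 0.5,
    span: float = 7.0,
    seed: int | np.random.Generator = 0,
    n_neighbors: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Ensemble of 1-D isomap embeddings on random gene half-subsets.

    ``submatrix`` is genes x samples (the window's selected genes).  Gene
    profiles are standardized; each iteration embeds the samples with a 1-D
    isomap on a random ``subset_fraction`` of the genes, orients the axis so
    it correlates non-negatively (Spearman) with collection time, and
    min-max scales it to ``[0, span]``.  The returned coordinate is the
    per-sample mean across iterations.  If the neighbourhood graph is
    disconnected the neighbour count is increased until connected (logged in
    the diagnostics).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    G, n = submatrix.shape
    if G < 2:
        raise ValueError("need at least two selected genes")
    if n < 5:
        raise ValueError("need at least five samples to embed")
    vals = submatrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]

    base_nn = n_neighbors or max(5, int(np.ceil(n / 10)))
    base_nn = min(base_nn, n - 1)
    n_genes_iter = max(1, int(round(subset_fraction * G)))
    coords = np.zeros(n)
    adjustments = 0
    prev_orient = 1.0
    for _ in range(n_iterations):
        idx = rng.choice(G, size=n_genes_iter, replace=False)
        X = Z[idx].T  # samples x genes subset
        nn = _connected_n_neighbors(X, base_nn)
        if nn != base_nn:
            adjustments += 1
        emb = Isomap(n_neighbors=nn, n_components=1).fit_transform(X)[:, 0]
        rho = stats.spearmanr(emb, t).statistic
        if np.isnan(rho) or rho == 0:
            orient = prev_orient
        else:
            orient = np.sign(rho)
        prev_orient = orient
        emb = emb * orient
        lo, hi = emb.min(), emb.max()
        if hi > lo:
            emb = (emb - lo) / (hi - lo) * span
        else:
            emb = np.full(n, span / 2.0)
        coords += emb
    coords /= n_iterations
    diag = {"n_neighbors": base_nn, "neighbor_adjust_iterations": adjustments}
    return coords, diag


def consensus_pseudotime(
    window_estimates: list[WindowEstimate],
    sample_ids: list[str] | pd.Index,
    weight_mode: str = "sum_neglog10",
) -> pd.DataFrame:
    """Weighted consensus of the per-window pseudotime estimates.

    Each window's weight is the sum over its selected genes of
    ``-log10(p_adjusted)`` (capped per gene), so both the number and the
    significance of supporting genes count.  Samples whose windows all carry
    zero weight fall back to the unweighted mean.
    """
    est: dict[str, list[tuple[float, float]]] = {str(s): [] for s in sample_ids}
    for w in window_estimates:
        for sid, pt in zip(w.sample_ids, w.pseudotimes):
            est[str(sid)].append((pt, w.weight))
    rows = []
    for sid in sample_ids:
        pairs = est[str(sid)]
        if not pairs:
            raise ValueError(f"sample {sid} is covered by no window")
        pts = np.array([p for p, _ in pairs])
        wts = np.array([w for _, w in pairs])
        if wts.sum() > 0:
            pt = float(np.sum(pts * wts) / wts.sum())
        else:
            warnings.warn(f"zero total weight for sample {sid}; unweighted mean",
                          stacklevel=2)
            pt = float(pts.mean())
        rows.append((str(sid), pt, len(pairs), float(wts.sum())))
    return pd.DataFrame(
        rows, columns=["sample_id", "pseudotime", "n_windows", "total_weight"]
    ).set_index("sample_id")


def window_weight(p_adjusted: pd.Series, mode: str = "sum_neglog10") -> float:
    p = np.clip(p_adjusted.to_numpy(dtype=float), 10.0 ** (-NEGLOG10_P_CAP), 1.0)
    neglog = np.minimum(-np.log10(p), NEGLOG10_P_CAP)
    if mode == "sum_neglog10":
        return float(np.sum(neglog))
    if mode == "n_times_median":
        return float(len(p) * np.median(neglog)) if len(p) else 0.0
    raise ValueError(f"unknown weight mode {mode!r}")


def median_collection_spread(
    pseudotime: pd.Series, collection_time: pd.Series
) -> tuple[pd.Series, float]:
    """Central-50% spread of pseudotime per collection hour and its median.

    For each collection time point with at least two samples, the spread is
    the range (max - min) of the central 50% of consensus pseudotimes (the
    values between the 25th and 75th percentiles, inclusive).  Points with a
    single sample are excluded.
    """
    pseudotime = pd.Series(pseudotime)
    collection_time = pd.Series(collection_time).reindex(pseudotime.index)
    spreads = {}
    for tp, grp in pseudotime.groupby(collection_time):
        if len(grp) < 2:
            continue
        v = np.sort(grp.to_numpy())
        q1, q3 = np.percentile(v, [25, 75])
        central = v[(v >= q1) & (v <= q3)]
        spreads[tp] = float(central.max() - central.min()) if len(central) else 0.0
    if not spreads:
        raise ValueError("no collection point has two or more samples")
    series = pd.Series(spreads, name="spread_h").sort_index()
    return series, float(series.median())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PseudotimeModel:
    """Consensus pseudotime estimator for one condition's time course.

    Parameters
    ----------
    matrix
        Preprocessed (log2, batch-corrected) expression matrix with
        ``collection_time`` sample metadata.
    variable_fraction
        Fraction of genes kept by the mean-variance trend filter.
    n_components, component_alpha
        Number of leading principal components screened against collection
        time, and the FDR threshold for keeping them.
    window_starts, window_span
        Start hours (default 1..16) and span (default 7 h) of the half-open
        selection windows.
    k_window, gamma_window, window_alpha
        Spline basis dimension, GCV penalty inflation and FDR threshold of
        the per-window gene selection.
    n_iterations, subset_fraction
        Isomap ensemble size and gene subset fraction per iteration.
    use_denoised_windows
        Run the window-wise gene selection on the component-denoised matrix
        (default) or on the raw filtered one.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        variable_fraction: float = 0.5,
        n_components: int = 50,
        component_alpha: float = 0.05,
        window_starts: np.ndarray | None = None,
        window_span: float = 7.0,
        k_window: int = 4,
        gamma_window: float = 1.25,
        window_alpha: float = 0.05,
        n_iterations: int = 100,
        subset_fraction: float = 0.5,
        weight_mode: str = "sum_neglog10",
        min_window_samples: int = 8,
        use_denoised_windows: bool = True,
    ):
        if matrix.scale != "log2":
            raise ValueError("PseudotimeModel expects a log2-scale matrix")
        self.matrix = matrix
        self.t = matrix.samples["collection_time"].to_numpy(dtype=float)
        if np.isnan(self.t).any():
            raise ValueError("every sample needs a collection_time")
        self.variable_fraction = variable_fraction
        self.n_components = n_components
        self.component_alpha = component_alpha
        if window_starts is None:
            t_max = np.nanmax(self.t)
            last_start = max(1, int(round(t_max)) - int(round(window_span)) + 1)
            window_starts = np.arange(1, last_start + 1, dtype=float)
        self.window_starts = np.asarray(window_starts, dtype=float)
        self.window_span = float(window_span)
        self.k_window = k_window
        self.gamma_window = gamma_window
        self.window_alpha = window_alpha
        self.n_iterations = n_iterations
        self.subset_fraction = subset_fraction
        self.weight_mode = weight_mode
        self.min_window_samples = min_window_samples
        self.use_denoised_windows = use_denoised_windows

    def fit(self, seed: int = 0) -> "PseudotimeResults":
        rng = np.random.default_rng(seed)
        genes = select_variable_genes(self.matrix, self.variable_fraction)
        filtered = self.matrix.subset_genes(genes)
        denoised, comp_report = denoise_by_time_components(
            filtered, self.t, n_components=self.n_components,
            alpha=self.component_alpha,
        )
        source = denoised if self.use_denoised_windows else filtered

        estimates: list[WindowEstimate] = []
        diagnostics: dict = {
            "n_variable_genes": len(genes),
            "n_components_kept": int(comp_report["kept"].sum()),
            "windows": [],
        }
        for ws in self.window_starts:
            hi = ws + self.window_span
            sel = window_gene_selection(
                source, self.t, (ws, hi), k=self.k_window,
                gamma=self.gamma_window, alpha=self.window_alpha,
                min_samples=self.min_window_samples,
            )
            win_diag = {"start": float(ws), "n_selected": 0, "skipped": True}
            if sel is not None and len(sel) >= 2:
                in_win = (self.t >= ws) & (self.t < hi)
                sub = source.values.loc[sel.index, source.sample_ids[in_win]]
                coords, emb_diag = ensemble_embedding(
                    sub, self.t[in_win], n_iterations=self.n_iterations,
                    subset_fraction=self.subset_fraction,
                    span=self.window_span, seed=rng,
                )
                estimates.append(
                    WindowEstimate(
                        window_start=float(ws),
                        window_span=self.window_span,
                        sample_ids=[str(s) for s in source.sample_ids[in_win]],
                        coordinates=coords,
                        weight=window_weight(sel, self.weight_mode),
                        selected_genes=sel,
                    )
                )
                win_diag = {"start": float(ws), "n_selected": int(len(sel)),
                            "skipped": False, **emb_diag}
            diagnostics["windows"].append(win_diag)

        if not estimates:
            raise ValueError(
                "no usable window: too few samples or no time-informative genes"
            )
        covered = set()
        for est in estimates:
            covered.update(est.sample_ids)
        all_ids = [str(s) for s in self.matrix.sample_ids]
        uncovered = [s for s in all_ids if s not in covered]
        table = consensus_pseudotime(
            estimates, [s for s in all_ids if s in covered], self.weight_mode
        )
        if uncovered:
            # samples whose only windows were skipped keep their collection
            # time as a zero-weight placeholder
            warnings.warn(
                f"{len(uncovered)} sample(s) covered by no window; "
                "falling back to collection time", stacklevel=2,
            )
            ct = self.matrix.samples["collection_time"]
            fallback = pd.DataFrame(
                {
                    "pseudotime": ct.loc[uncovered].astype(float),
                    "n_windows": 0,
                    "total_weight": 0.0,
                },
            )
            fallback.index.name = "sample_id"
            table = pd.concat([table, fallback]).loc[all_ids]
        diagnostics["n_uncovered_samples"] = len(uncovered)
        return PseudotimeResults(self, table, estimates, comp_report, diagnostics)


@dataclass
class PseudotimeResults:
    """Fitted consensus pseudotime with per-window detail."""

    model: PseudotimeModel
    table: pd.DataFrame  # sample_id -> pseudotime, n_windows, total_weight
    window_estimates: list[WindowEstimate]
    component_report: pd.DataFrame
    diagnostics: dict

    @property
    def pseudotime(self) -> pd.Series:
        return self.table["pseudotime"]

    def median_collection_spread(self) -> tuple[pd.Series, float]:
        return median_collection_spread(
            self.pseudotime, self.model.matrix.samples["collection_time"]
        )

    def ordered_sample_ids(self) -> list[str]:
        return list(self.table.sort_values("pseudotime").index)

    def summary(self) -> str:
        spread, med = self.median_collection_spread()
        lines = [
            "Consensus pseudotime",
            "====================",
            f"samples:                 {len(self.table)}",
            f"variable genes kept:     {self.diagnostics['n_variable_genes']}",
            f"time components kept:    {self.diagnostics['n_components_kept']}",
            f"windows used:            {len(self.window_estimates)}"
            f" / {len(self.model.window_starts)}",
            f"windows per sample:      {self.table['n_windows'].min()}-"
            f"{self.table['n_windows'].max()}",
            f"median spread per point: {med:.2f} h",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
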