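"""Count-table preprocessing: depth filter, size factors, log transform,
moving-average smoothing and the mutual-nearest-neighbour batch correction.

The normalization is deliberately robust to a handful of very highly
expressed genes: the top 5 percentiles of genes (by mean expression) are
excluded from the size-factor sums.  The batch correction exploits the
asynchrony of the two collection sessions: samples collected at 10-11 h in
the first session overlap developmentally with samples collected at 12-13 h
in the second, so their mutual nearest neighbours (by Spearman correlation)
estimate per-gene additive log2 shifts between sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "BatchShifts",
    "filter_low_depth",
    "compute_size_factors",
    "normalize_counts",
    "log_transform",
    "mnn_batch_correct",
    "moving_average",
    "preprocess",
]

DEFAULT_MIN_READS = 5_000_000
DEFAULT_PSEUDOCOUNT = 8.0
DEFAULT_MNN_K = 3


@dataclass
class BatchShifts:
    """Per-gene log2 shifts estimated from MNN bridge pairs."""

    shifts: pd.Series
    mnn_pairs: list[tuple[str, str]]
    n_pairs: int

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "shift_mean": float(self.shifts.mean()),
            "shift_sd": float(self.shifts.std()),
            "shift_abs_mean": float(self.shifts.abs().mean()),
        }


def filter_low_depth(
    matrix: ExpressionMatrix, min_reads: float = DEFAULT_MIN_READS
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose library size is below ``min_reads``."""
    lib = matrix.samples["library_size"]
    if lib.isna().any():
        lib = lib.fillna(matrix.values.sum(axis=0))
    keep = lib >= min_reads
    removed = list(matrix.sample_ids[~keep])
    if keep.sum() == 0:
        raise ValueError("all samples fall below the library-size threshold")
    return matrix.subset_samples(matrix.sample_ids[keep]), removed


def compute_size_factors(
    matrix: ExpressionMatrix, exclude_top_percentile: float = 5.0
) -> pd.Series:
    """Per-sample size factors from counts, robust to dominant genes.

    Genes in the top ``exclude_top_percentile`` percentiles of mean
    expression across samples form one global exclusion set; each sample's
    factor is proportional to its count sum over the remaining genes, scaled
    to mean 1.
    """
    if matrix.scale != "counts":
        raise ValueError("size factors are computed on raw counts")
    counts = matrix.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-count sample(s) present")
    mean_expr = counts.mean(axis=1)
    cutoff = np.percentile(mean_expr, 100.0 - exclude_top_percentile)
    included = mean_expr < cutoff
    if not included.any():
        included = np.ones_like(included, dtype=bool)
    sums = counts[included].sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("a sample has zero counts outside the excluded genes")
    factors = sums / sums.mean()
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize_counts(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide counts by size factors and rescale to a CPM-like unit.

    After division by the factor, all samples are put on a common
    counts-per-million scale (the mean per-sample total maps to 1e6).
    """
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every sample")
    scaled = matrix.values.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    scaled *= 1e6 / scaled.sum(axis=0).mean()
    out = matrix.copy()
    out.values = pd.DataFrame(scaled, index=matrix.gene_ids, columns=matrix.sample_ids)
    out.scale = "normalized"
    return out


def log_transform(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """``log2(value + pseudocount)``; the pseudocount (default 8) shrinks the
    apparent effect sizes of lowly expressed genes."""
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("log transform requires non-negative values")
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.log2(vals + pseudocount), index=matrix.gene_ids, columns=matrix.sample_ids
    )
    out.scale = "log2"
    return out


def mnn_batch_correct(
    matrix: ExpressionMatrix,
    batch_labels: pd.Series | None = None,
    bridge_a: tuple[float, float] = (10.0, 11.0),
    bridge_b: tuple[float, float] = (12.0, 13.0),
    k: int = DEFAULT_MNN_K,
    symmetric: bool = False,
) -> tuple[ExpressionMatrix, BatchShifts]:
    """Remove the between-session batch shift using mutual nearest neighbours.

    Bridge samples are those of the first batch collected in the
    ``bridge_a`` hour range and those of the second batch in ``bridge_b``.
    All cross-batch bridge pairs are ranked by Spearman correlation; a pair
    is an MNN when each sample is among the other's top ``k``.  The per-gene
    shift is the mean over MNN pairs of (batch-B value - batch-A value) and
    is subtracted from every batch-B sample (or split half-and-half between
    the batches when ``symmetric``).
    """
    if matrix.scale != "log2":
        raise ValueError("MNN correction expects log2-scale values")
    if batch_labels is None:
        batch_labels = matrix.samples["batch"]
    batch_labels = pd.Series(batch_labels).reindex(matrix.sample_ids)
    levels = sorted(batch_labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError("expected exactly two batches")
    la, lb = levels
    ct = matrix.samples["collection_time"]
    ids_a = matrix.sample_ids[
        (batch_labels == la) & ct.between(bridge_a[0], bridge_a[1])
    ]
    ids_b = matrix.sample_ids[
        (batch_labels == lb) & ct.between(bridge_b[0], bridge_b[1])
    ]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("empty bridge set; cannot anchor the batch correction")

    va = matrix.values[ids_a].to_numpy(dtype=float)
    vb = matrix.values[ids_b].to_numpy(dtype=float)
    rho = stats.spearmanr(np.hstack([va, vb]))[0]
    if np.isscalar(rho):  # two samples total
        rho = np.array([[1.0, rho], [rho, 1.0]])
    cross = rho[: len(ids_a), len(ids_a):]  # A rows x B columns

    k_eff = min(k, len(ids_a), len(ids_b))
    top_b_for_a = np.argsort(-cross, axis=1)[:, :k_eff]
    top_a_for_b = np.argsort(-cross, axis=0)[:k_eff, :]
    pairs = []
    for i in range(len(ids_a)):
        for j in top_b_for_a[i]:
            if i in top_a_for_b[:, j]:
                pairs.append((i, j))
    if not pairs:
        raise ValueError("no mutual nearest neighbours found across batches")
    if len(pairs) < 3:
        warnings.warn(
            f"only {len(pairs)} MNN pair(s) support the batch correction",
            stacklevel=2,
        )

    diffs = np.stack([vb[:, j] - va[:, i] for i, j in pairs], axis=1)
    shift = diffs.mean(axis=1)

    out = matrix.copy()
    block = out.values.to_numpy(dtype=float)
    mask_b = (batch_labels == lb).to_numpy()
    if symmetric:
        block[:, mask_b] -= shift[:, None] / 2.0
        block[:, ~mask_b] += shift[:, None] / 2.0
    else:
        block[:, mask_b] -= shift[:, None]
    out.values = pd.DataFrame(block, index=matrix.gene_ids, columns=matrix.sample_ids)
    named_pairs = [(str(ids_a[i]), str(ids_b[j])) for i, j in pairs]
    shifts = BatchShifts(
        shifts=pd.Series(shift, index=matrix.gene_ids, name="shift_log2"),
        mnn_pairs=named_pairs,
        n_pairs=len(named_pairs),
    )
    return out, shifts


def moving_average(series, window: int):
    """Centered moving mean with truncated windows at the edges.

    For index i the window covers ``[i - floor((w-1)/2), i + ceil((w-1)/2)]``
    intersected with the series; output length equals input length.  A
    window larger than the series yields the global mean everywhere.
    Works on 1-D arrays or along the columns (samples axis) of a 2-D
    genes x samples array.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x.reshape(1, -1)
    n = x.shape[1]
    lo_off = (window - 1) // 2
    hi_off = window - 1 - lo_off
    csum = np.concatenate(
        [np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1
    )
    starts = np.maximum(np.arange(n) - lo_off, 0)
    stops = np.minimum(np.arange(n) + hi_off + 1, n)
    out = (csum[:, stops] - csum[:, starts]) / (stops - starts)
    if one_d:
        out = out.ravel()
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(out, index=series.index, columns=series.columns)
    return out


def preprocess(
    matrix: ExpressionMatrix,
    min_reads: float = DEFAULT_MIN_READS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mnn_k: int = DEFAULT_MNN_K,
    batch_correct: bool = True,
    bridge_a: tuple[float, float] = (10.0, 11.0),
    bridge_b: tuple[float, float] = (12.0, 13.0),
) -> tuple[ExpressionMatrix, dict]:
    """Full chain: depth filter -> size factors -> CPM -> log2 -> MNN.

    Returns the corrected log2 matrix and a report dictionary (removed
    samples, exclusion-set size, MNN pair count, shift summary).
    """
    filtered, removed = filter_low_depth(matrix, min_reads=min_reads)
    factors = compute_size_factors(filtered)
    norm = normalize_counts(filtered, factors)
    logm = log_transform(norm, pseudocount=pseudocount)
    report: dict = {
        "n_samples_in": matrix.n_samples,
        "removed_samples": removed,
        "n_removed": len(removed),
    }
    if batch_correct and filtered.samples["batch"].nunique() == 2:
        corrected, shifts = mnn_batch_correct(
            logm, bridge_a=bridge_a, bridge_b=bridge_b, k=mnn_k
        )
        report["mnn"] = shifts.summary()
        return corrected, report
    return logm, report
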