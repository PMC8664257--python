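"""Projection of spheroid and regenerated-animal transcriptomes onto the
positional-identity subspace defined by adult body segments.

The axial body plan (head .. foot) spans a low-dimensional expression
subspace.  A PCA basis fitted on segment transcriptomes (mean-centred,
unscaled) defines that subspace; pseudotime-ordered spheroid trajectories
and whole regenerated animals are projected onto it to read out positional
identity.  Only genes changing at least twofold (|max - min| of log2 values
>= 1) in both the segment and the spheroid data enter the basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .preprocessing import moving_average

__all__ = [
    "SubspaceModel",
    "EllipseSpec",
    "select_projection_genes",
    "fit_segment_basis",
    "confidence_ellipse",
]


def select_projection_genes(
    segments: ExpressionMatrix,
    spheroids: ExpressionMatrix,
    min_delta: float = 1.0,
) -> list[str]:
    """Genes with a log2 range >= ``min_delta`` in both datasets.

    ``min_delta = 1`` corresponds to at least a twofold change.  Raises when
    the intersection is empty.
    """
    shared = segments.gene_ids.intersection(spheroids.gene_ids)
    if len(shared) == 0:
        raise ValueError("segment and spheroid matrices share no genes")
    seg = segments.values.loc[shared]
    sph = spheroids.values.loc[shared]
    rng_seg = seg.max(axis=1) - seg.min(axis=1)
    rng_sph = sph.max(axis=1) - sph.min(axis=1)
    keep = shared[(rng_seg >= min_delta) & (rng_sph >= min_delta)]
    if len(keep) == 0:
        raise ValueError("no gene passes the twofold-change filter in both datasets")
    return list(keep)


@dataclass
class EllipseSpec:
    """Gaussian confidence ellipse of a 2-D point cloud."""

    center: np.ndarray
    axis_lengths: np.ndarray  # semi-axes, sqrt(eigenvalue * chi2 quantile)
    rotation_deg: float
    level: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis membership test for an array of 2-D points."""
        theta = np.deg2rad(self.rotation_deg)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        local = (np.atleast_2d(points) - self.center) @ R
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (local / self.axis_lengths) ** 2
        return q.sum(axis=1) <= 1.0 + 1e-12


def confidence_ellipse(scores: np.ndarray, level: float = 0.9) -> EllipseSpec:
    """Ellipse covering ``level`` of a bivariate Gaussian fitted to scores.

    Semi-axes are ``sqrt(eigenvalue * chi2_2(level))`` of the sample
    covariance.  Collinear point sets are returned flagged degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an n x 2 array")
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 points for a covariance ellipse")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1e-300))
    axis_lengths = np.sqrt(np.maximum(evals, 0.0) * q)
    rotation = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return EllipseSpec(center, axis_lengths, rotation, level, degenerate)


class SubspaceModel:
    """Positional-identity eigenbasis fitted on segment transcriptomes.

    Attributes
    ----------
    gene_subset : list of genes the basis is defined on
    center : per-gene mean of the training (segment) data
    components : eigenvectors as rows, ordered by explained variance
    explained_variance_ratio : fraction of training variance per component
    centroids : per-segment-label mean scores (training groups)
    """

    def __init__(self, gene_subset, center, components, explained_variance_ratio,
                 centroids, training_scores):
        self.gene_subset = list(gene_subset)
        self.center = center
        self.components = components
        self.explained_variance_ratio = explained_variance_ratio
        self.centroids = centroids
        self.training_scores = training_scores

    def project(
        self,
        data: ExpressionMatrix | pd.DataFrame,
        smooth_window: int | None = None,
        n_dims: int = 2,
    ) -> pd.DataFrame:
        """Project samples onto the segment eigenbasis.

        ``smooth_window`` applies a centred moving average along the column
        order before projection — pass the pseudotime-ordered spheroid
        matrix and a window of 16 samples (~2 h of pseudotime); leave it
        ``None`` (or 1) for unordered data such as whole regenerated
        animals.  Scores are ``(smoothed - center) @ eigenvectors``.
        """
        values = data.values if isinstance(data, ExpressionMatrix) else data
        missing = [g for g in self.gene_subset if g not in values.index]
        if missing:
            raise ValueError(
                f"{len(missing)} basis genes missing from data, e.g. {missing[:5]}"
            )
        sub = values.loc[self.gene_subset]
        if smooth_window is not None and smooth_window > 1:
            sub = moving_average(sub, smooth_window)
        X = sub.to_numpy(dtype=float).T - self.center
        scores = X @ self.components.T
        n_dims = min(n_dims, scores.shape[1])
        return pd.DataFrame(
            scores[:, :n_dims],
            index=sub.columns,
            columns=[f"PC{i + 1}" for i in range(n_dims)],
        )

    def group_ellipses(self, level: float = 0.9) -> dict[str, EllipseSpec]:
        """Confidence ellipses of the training groups in PC1-PC2."""
        out = {}
        for label, grp in self.training_scores.groupby("group"):
            pts = grp[["PC1", "PC2"]].to_numpy()
            if len(pts) >= 3:
                out[label] = confidence_ellipse(pts, level)
        return out


def fit_segment_basis(
    segments: ExpressionMatrix,
    gene_subset: list[str] | None = None,
    group_column: str = "segment",
) -> SubspaceModel:
    """Mean-centred (unscaled) PCA of the segment data.

    All replicates enter the PCA (not the centroids), preserving the
    within-group variance that the confidence ellipses visualise.
    Eigenvector signs are fixed so each component's largest-magnitude gene
    loading is positive.
    """
    if segments.n_samples < 3:
        raise ValueError("need at least 3 segment samples")
    mat = segments.values if gene_subset is None else segments.values.loc[gene_subset]
    genes = list(mat.index)
    X = mat.to_numpy(dtype=float).T  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = U * s
    groups = (
        segments.samples[group_column]
        if group_column in segments.samples.columns
        else pd.Series("all", index=segments.sample_ids)
    )
    training = pd.DataFrame(
        scores[:, : min(scores.shape[1], 10)],
        index=segments.sample_ids,
        columns=[f"PC{i + 1}" for i in range(min(scores.shape[1], 10))],
    )
    training["group"] = groups.to_numpy()
    centroids = training.groupby("group").mean(numeric_only=True)
    return SubspaceModel(genes, center, Vt, evr, centroids, training)
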