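"""Small plotting helpers for traces and subspace projections."""

from __future__ import annotations

import numpy as np

from .containers import RadiusTrace
from .oscillation import CycleTable
from .projection import SubspaceModel


def plot_trace(trace: RadiusTrace, table: CycleTable | None = None, ax=None):
    """Normalized radius trace with detected cycle peaks and troughs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.time, trace.radius, lw=0.8, color="0.2")
    if table is not None:
        for c in table.cycles:
            ax.axvline(trace.time[c.end_index], color="tab:red", lw=0.5, alpha=0.5)
            ax.plot(trace.time[c.peak_index], trace.radius[c.peak_index], "v",
                    color="tab:blue", ms=4)
        if table.transition_index is not None:
            c = table.cycles[table.transition_index - 1]
            ax.axvline(trace.time[c.start_index], color="tab:green", ls="--",
                       label="phase I/II transition")
            ax.legend(frameon=False)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("radius (norm.)")
    return ax


def plot_projection(
    model: SubspaceModel,
    sample_scores=None,
    pseudotime=None,
    levels=(0.9, 0.8, 0.7),
    ax=None,
):
    """Segment groups with nested confidence ellipses, plus projected samples.

    ``sample_scores`` is a PC1/PC2 frame (e.g. from ``model.project``);
    ``pseudotime`` (same index) shades the samples from early (light) to
    late (dark).
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for gi, (label, grp) in enumerate(model.training_scores.groupby("group")):
        pts = grp[["PC1", "PC2"]].to_numpy()
        ax.scatter(pts[:, 0], pts[:, 1], s=12, color=cmap(gi % 10), label=label)
        if len(pts) >= 3:
            from .projection import confidence_ellipse

            for li, level in enumerate(sorted(levels, reverse=True)):
                spec = confidence_ellipse(pts, level)
                if spec.degenerate:
                    continue
                ax.add_patch(
                    Ellipse(
                        spec.center,
                        2 * spec.axis_lengths[0],
                        2 * spec.axis_lengths[1],
                        angle=spec.rotation_deg,
                        facecolor=cmap(gi % 10),
                        alpha=0.08 + 0.05 * li,
                        edgecolor="none",
                    )
                )
    if sample_scores is not None:
        shade = None
        if pseudotime is not None:
            pt = np.asarray(pseudotime, dtype=float)
            rng = np.ptp(pt)
            shade = (pt - pt.min()) / rng if rng > 0 else np.zeros_like(pt)
        ax.scatter(
            sample_scores["PC1"],
            sample_scores["PC2"],
            c=shade if shade is not None else "0.3",
            cmap="Greys",
            s=10,
            marker="x",
            label="samples",
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    return ax
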