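"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "RadiusTrace"]

SAMPLE_COLUMNS = ("collection_time", "condition", "batch", "library_size")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample metadata.

    ``values`` is a genes-by-samples DataFrame (raw counts, CPM-like
    normalized values, or log2 values — tracked by ``scale``).  ``samples``
    is indexed by sample id and carries ``collection_time`` (hours),
    ``condition``, ``batch`` and ``library_size`` where known.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "counts"  # counts | normalized | log2

    def __post_init__(self):
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample metadata does not match matrix columns")
            self.samples = self.samples.loc[self.values.columns]
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, sample_ids], self.samples.loc[sample_ids], self.scale
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.samples, self.scale)

    # ---- I/O ---------------------------------------------------------------

    def to_tsv(self, values_path, samples_path=None) -> None:
        values_path = Path(values_path)
        self.values.to_csv(values_path, sep="\t")
        if samples_path is None:
            samples_path = values_path.with_name(values_path.stem + ".samples.tsv")
        self.samples.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, samples_path=None, scale="counts") -> "ExpressionMatrix":
        values_path = Path(values_path)
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        if samples_path is None:
            samples_path = values_path.with_name(values_path.stem + ".samples.tsv")
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, samples, scale)

    def to_mtx(self, out_dir) -> None:
        from scipy import io as spio
        from scipy import sparse

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(out_dir / "matrix.mtx", sparse.csr_matrix(self.values.to_numpy()))
        pd.Series(self.gene_ids).to_csv(
            out_dir / "genes.tsv", sep="\t", index=False, header=False
        )
        self.samples.to_csv(out_dir / "samples.tsv", sep="\t")

    @classmethod
    def from_mtx(cls, in_dir, scale="counts") -> "ExpressionMatrix":
        from scipy import io as spio

        in_dir = Path(in_dir)
        mat = spio.mmread(in_dir / "matrix.mtx").toarray()
        genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0]
        samples = pd.read_csv(in_dir / "samples.tsv", sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        values = pd.DataFrame(mat, index=genes, columns=samples.index)
        return cls(values, samples, scale)


@dataclass
class RadiusTrace:
    """Uniformly sampled lumen-radius time series, normalized to its start.

    ``time`` is in hours on a uniform grid (default spacing 10 min) and
    ``radius`` is dimensionless, with ``radius[0] == 1`` after normalization.
    """

    time: np.ndarray
    radius: np.ndarray
    sample_id: str = "trace"
    condition: str | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.time.shape != self.radius.shape:
            raise ValueError("time and radius must have the same length")
        if len(self.time) >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else np.nan

    def normalized(self) -> "RadiusTrace":
        """Return a copy with radius divided by its first value."""
        if self.radius[0] == 0:
            raise ValueError("cannot normalize a trace starting at zero radius")
        return RadiusTrace(
            self.time.copy(),
            self.radius / self.radius[0],
            self.sample_id,
            self.condition,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.time, "radius_norm": self.radius}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, sample_id=None, condition=None) -> "RadiusTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy(),
            df["radius_norm"].to_numpy(),
            sample_id or Path(path).stem,
            condition,
        )
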