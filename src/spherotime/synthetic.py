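"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's raw material: sawtooth lumen-radius
traces of inflating/deflating spheroids, bright-field-like images of a
spheroid cross-section, and asynchronous two-condition / two-batch bulk
RNA-seq time courses.  A fourth produces axial (head-to-foot) segment
expression profiles.  Each generator records the ground truth needed by
recovery tests, and all are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, RadiusTrace

__all__ = [
    "OscillationSimConfig",
    "ExpressionSimConfig",
    "GroundTruth",
    "generate_oscillation_trace",
    "generate_spheroid_image",
    "generate_expression_timecourse",
    "generate_segment_profiles",
    "inject_batch_effect",
]

ISOTONIC_MM = 70.0  # sucrose-equivalent osmolarity at which inflation stops


# ---------------------------------------------------------------------------
# oscillation traces
# ---------------------------------------------------------------------------

@dataclass
class OscillationSimConfig:
    """Parameters of the simulated inflation/deflation sawtooth.

    ``slope`` is the inflation rate (normalized radius per hour) in plain
    medium (0 mM sucrose); the effective rate scales linearly to zero at the
    isotonic point (70 mM), mirroring concentration-dependent slowing of
    osmotic inflation.  Phase II follows phase I with amplitude and period
    shrunk by the two factors.
    """

    n_cycles_phase1: int = 4
    n_cycles_phase2: int = 4
    slope: float = 0.0625
    rupture_threshold: float = 1.5
    deflation_floor: float = 1.0
    phase2_amplitude_factor: float = 0.4
    phase2_period_factor: float = 0.4
    osmolarity: float = 0.0
    noise_sd: float = 0.0
    dt: float = 1.0 / 6.0  # hours; 10-min frame interval
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.osmolarity <= ISOTONIC_MM):
            raise ValueError(f"osmolarity must lie in [0, {ISOTONIC_MM}] mM")
        if not (self.rupture_threshold > self.deflation_floor >= 1.0):
            raise ValueError("need rupture_threshold > deflation_floor >= 1")
        if not (0 < self.phase2_amplitude_factor < 1):
            raise ValueError("phase2_amplitude_factor must lie in (0, 1)")
        if not (0 < self.phase2_period_factor < 1):
            raise ValueError("phase2_period_factor must lie in (0, 1)")
        if self.slope < 0 or self.noise_sd < 0:
            raise ValueError("slope and noise_sd must be non-negative")

    @property
    def effective_slope(self) -> float:
        """Inflation rate after osmotic slowing; zero at isotonic."""
        return self.slope * (1.0 - self.osmolarity / ISOTONIC_MM)


def generate_oscillation_trace(config: OscillationSimConfig) -> RadiusTrace:
    """Simulate a normalized lumen-radius trace.

    Phase I consists of ``n_cycles_phase1`` linear rises from the deflation
    floor toward the rupture threshold.  Rupture is instantaneous and occurs
    between frames: the first sample at or past threshold already shows the
    deflation floor, so the exact threshold value is never emitted (as with
    a 10-min camera interval in the real assay).  Phase II repeats the
    pattern with scaled amplitude and period.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.slope <= 0:
        raise ValueError("slope must be positive to define a trace duration")
    thr, floor = config.rupture_threshold, config.deflation_floor
    amp1 = thr - floor
    s_eff = config.effective_slope

    # cycle boundaries in continuous time; the first cycle starts at the
    # normalized initial radius 1.0, later cycles at the deflation floor
    slope_for_layout = s_eff if s_eff > 0 else config.slope
    amp2 = amp1 * config.phase2_amplitude_factor
    period1 = amp1 / slope_for_layout
    period2 = period1 * config.phase2_period_factor
    slope2 = amp2 / period2
    bounds, starts, slopes = [0.0], [], []
    cur = 0.0
    for c in range(config.n_cycles_phase1):
        start = 1.0 if c == 0 else floor
        cur += (thr - start) / slope_for_layout
        starts.append(start)
        slopes.append(s_eff)
        bounds.append(cur)
    for _ in range(config.n_cycles_phase2):
        cur += period2
        starts.append(floor)
        slopes.append(s_eff * config.phase2_amplitude_factor
                      / config.phase2_period_factor)
        bounds.append(cur)

    # terminal segment: the trace ends on the last collapse, at the floor
    starts.append(floor)
    slopes.append(0.0)

    n = int(np.floor(bounds[-1] / config.dt + 1e-9)) + 1
    time = np.arange(n) * config.dt

    if s_eff <= 0:
        radius = np.ones(n)
    else:
        eps = config.dt * 1e-6
        b = np.asarray(bounds)
        idx = np.clip(np.searchsorted(b, time + eps, side="right") - 1,
                      0, len(starts) - 1)
        radius = (np.asarray(starts)[idx]
                  + np.asarray(slopes)[idx] * (time - b[idx]))
        radius = np.minimum(radius, thr)
        radius[0] = 1.0

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=n)
        noise[0] = 0.0  # trace is normalized to its first frame
        radius = radius + noise

    return RadiusTrace(time, radius, sample_id=f"sim-{config.seed}")


# ---------------------------------------------------------------------------
# spheroid images
# ---------------------------------------------------------------------------

def generate_spheroid_image(
    outer_radius_px: float,
    lumen_radius_px: float,
    image_size: int = 512,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.85,
    tissue: float = 0.25,
    lumen: float = 0.55,
) -> np.ndarray:
    """Bright-field-like grayscale image of a spheroid cross section.

    A dark tissue annulus on a bright background, with the lumen interior
    dimmer than the background but brighter than the tissue.  Intensities are
    floats in [0, 1] before noise.
    """
    if not (0 <= lumen_radius_px < outer_radius_px < image_size / 2):
        raise ValueError("need lumen_radius_px < outer_radius_px < image_size / 2")
    rng = np.random.default_rng(seed)
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - c, xx - c)
    img = np.full((image_size, image_size), background, dtype=float)
    img[r <= outer_radius_px] = tissue
    if lumen_radius_px > 0:
        img[r <= lumen_radius_px] = lumen
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# expression time courses
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Study conditions of the simulated spheroid RNA-seq time course.

    Defaults mirror the two-condition (plain vs isotonic medium) 22-hour
    collection design: samples spread over a 1-hour collection grid, latent
    developmental time jittered around the collection time, smooth per-gene
    log2 trajectories, negative-binomial counts, two collection sessions that
    split the course in half and carry a log2 batch shift on a gene subset.
    """

    n_genes: int = 400
    n_dynamic: int = 60
    n_condition_divergent: int = 20
    n_samples_per_condition: int = 150
    time_span: float = 22.0
    asynchrony_sd: float = 1.5
    trajectory_family: str = "mixed"  # mixed | sigmoid | bump | linear | flat
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (6e6, 25e6)
    batch_fraction: float = 0.5
    batch_shift_sd: float = 0.5
    batch_affected_fraction: float = 0.2
    conditions: tuple[str, str] = ("control", "isotonic")
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if not (0 <= self.n_dynamic <= self.n_genes):
            raise ValueError("n_dynamic must not exceed n_genes")
        if not (0 <= self.n_condition_divergent <= self.n_dynamic):
            raise ValueError("n_condition_divergent must not exceed n_dynamic")
        if self.asynchrony_sd < 0:
            raise ValueError("asynchrony_sd must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.trajectory_family not in {"mixed", "sigmoid", "bump", "linear", "flat"}:
            raise ValueError(f"unknown trajectory_family {self.trajectory_family!r}")
        if self.library_size_range[1] > 2**31:
            raise ValueError("library sizes this large would overflow count storage")
        if not (0 < self.batch_fraction < 1):
            raise ValueError("batch_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    latent_time: pd.Series
    dynamic_gene_ids: list[str]
    divergent_gene_ids: list[str]
    batch_shifts: pd.Series
    expected_log2_cpm: pd.DataFrame | None = None
    segment_gradient_params: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "latent_time": self.latent_time.to_dict(),
            "dynamic_gene_ids": list(self.dynamic_gene_ids),
            "divergent_gene_ids": list(self.divergent_gene_ids),
            "batch_shifts": self.batch_shifts.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            latent_time=pd.Series(payload["latent_time"]),
            dynamic_gene_ids=payload["dynamic_gene_ids"],
            divergent_gene_ids=payload["divergent_gene_ids"],
            batch_shifts=pd.Series(payload["batch_shifts"]),
        )


def _trajectory_shapes(rng, n, family, span):
    """Per-gene smooth shape functions of latent time mapping to [0, 1]."""
    shapes = []
    for _ in range(n):
        fam = family
        if fam == "mixed":
            fam = rng.choice(["sigmoid", "bump"])
        if fam == "sigmoid":
            t0 = rng.uniform(0.2 * span, 0.8 * span)
            tau = rng.uniform(0.05 * span, 0.15 * span)
            shapes.append(("sigmoid", t0, tau))
        elif fam == "bump":
            t0 = rng.uniform(0.2 * span, 0.8 * span)
            w = rng.uniform(0.08 * span, 0.2 * span)
            shapes.append(("bump", t0, w))
        elif fam == "linear":
            shapes.append(("linear", 0.0, span))
        else:
            shapes.append(("flat", 0.0, 1.0))
    return shapes


def _eval_shape(shape, t):
    kind, a, b = shape
    t = np.asarray(t, dtype=float)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-(t - a) / b))
    if kind == "bump":
        return np.exp(-0.5 * ((t - a) / b) ** 2)
    if kind == "linear":
        return t / b
    return np.zeros_like(t)


def generate_expression_timecourse(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the asynchronous two-condition count time course.

    Samples are allocated evenly to the 1..time_span hourly collection grid;
    the latent developmental time of each spheroid is its collection time
    plus Gaussian asynchrony (clipped to the span).  Dynamic genes follow
    smooth log2-CPM trajectories of latent time; condition-divergent genes
    get an independent trajectory in the second condition.  Expected CPM
    columns are renormalized to sum to 1e6, counts are negative-binomial
    around library-scaled expectations (``dispersion == 0`` means
    deterministic expected counts), and second-session samples carry per-gene
    log2 batch shifts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    span = config.time_span
    hours = np.arange(1, int(round(span)) + 1)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    dynamic = genes[: config.n_dynamic]
    divergent = genes[: config.n_condition_divergent]

    base_log2 = rng.normal(5.0, 1.5, size=config.n_genes)
    amp = rng.uniform(1.5, 3.0, size=config.n_genes) * rng.choice(
        [-1.0, 1.0], size=config.n_genes
    )
    fams = _trajectory_shapes(rng, config.n_genes, config.trajectory_family, span)
    fams_alt = _trajectory_shapes(rng, config.n_condition_divergent,
                                  config.trajectory_family, span)
    amp_alt = rng.uniform(1.5, 3.0, size=config.n_condition_divergent) * rng.choice(
        [-1.0, 1.0], size=config.n_condition_divergent
    )

    affected = rng.random(config.n_genes) < config.batch_affected_fraction
    shifts = np.where(affected, rng.normal(0.0, config.batch_shift_sd,
                                           size=config.n_genes), 0.0)
    if config.batch_shift_sd == 0:
        shifts = np.zeros(config.n_genes)
    batch_split = round(span * (1.0 - config.batch_fraction))

    sample_ids, collection, latent, condition, batch = [], [], [], [], []
    columns = []
    lib_sizes = []
    for ci, cond in enumerate(config.conditions):
        for j in range(config.n_samples_per_condition):
            hour = int(hours[j % len(hours)])
            lat = float(np.clip(hour + rng.normal(0.0, config.asynchrony_sd), 0.0, span))
            sample_ids.append(f"{cond}_{j:03d}")
            collection.append(hour)
            latent.append(lat)
            condition.append(cond)
            batch.append("A" if hour <= batch_split else "B")
            lib_sizes.append(rng.uniform(*config.library_size_range))

            log2cpm = base_log2.copy()
            for gi in range(config.n_dynamic):
                if ci == 1 and gi < config.n_condition_divergent:
                    log2cpm[gi] += amp_alt[gi] * _eval_shape(fams_alt[gi], lat)
                else:
                    log2cpm[gi] += amp[gi] * _eval_shape(fams[gi], lat)
            columns.append(log2cpm)

    log2cpm_mat = np.column_stack(columns)  # genes x samples
    cpm = 2.0 ** log2cpm_mat
    cpm *= 1e6 / cpm.sum(axis=0, keepdims=True)
    expected_log2_cpm = pd.DataFrame(
        np.log2(cpm), index=genes, columns=sample_ids
    )

    lib = np.asarray(lib_sizes)
    mu = cpm * lib[None, :] / 1e6
    is_b = np.asarray(batch) == "B"
    mu[:, is_b] *= 2.0 ** shifts[:, None]

    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = mu.copy()

    values = pd.DataFrame(counts, index=genes, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "collection_time": collection,
            "condition": condition,
            "batch": batch,
            "library_size": lib,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(values, samples, scale="counts")
    truth = GroundTruth(
        latent_time=pd.Series(latent, index=sample_ids, name="latent_time"),
        dynamic_gene_ids=dynamic,
        divergent_gene_ids=divergent,
        batch_shifts=pd.Series(shifts, index=genes, name="batch_shift_log2"),
        expected_log2_cpm=expected_log2_cpm,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# axial segment profiles
# ---------------------------------------------------------------------------

SEGMENT_ORDER = ["head", "body1", "body2", "body3", "body4", "budding_zone", "foot"]


def generate_segment_profiles(
    n_genes: int = 200,
    n_segments: int = 7,
    n_replicates: int = 8,
    gradient_families: tuple[float, float, float] = (0.35, 0.35, 0.30),
    noise_sd: float = 0.25,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Axial body-segment expression profiles (log2 scale).

    ``gradient_families`` gives the fractions of head-enriched, foot-enriched
    and flat genes.  Head-enriched genes decrease strictly and monotonically
    from head to foot (and vice versa) in the noise-free limit.  Returns the
    log2 matrix with a ``segment`` sample column plus a per-gene parameter
    table (family, amplitude) serving as ground truth.  Pass ``gene_ids`` to
    share a gene namespace with a simulated time course; otherwise ids
    encode the family (e.g. ``head_0003``).
    """
    if gene_ids is not None:
        n_genes = len(gene_ids)
    if n_segments < 2:
        raise ValueError("need at least two segments")
    if n_replicates < 1:
        raise ValueError("need at least one replicate per segment")
    rng = np.random.default_rng(seed)
    segments = (
        SEGMENT_ORDER[:n_segments]
        if n_segments <= len(SEGMENT_ORDER)
        else [f"seg{i}" for i in range(n_segments)]
    )
    pos = np.linspace(0.0, 1.0, n_segments)  # 0 = head, 1 = foot

    f_head, f_foot, _ = gradient_families
    n_head = int(round(n_genes * f_head))
    n_foot = int(round(n_genes * f_foot))
    fam = ["head"] * n_head + ["foot"] * n_foot + ["flat"] * (n_genes - n_head - n_foot)
    base = rng.normal(6.0, 1.0, size=n_genes)
    amp = rng.uniform(1.5, 3.0, size=n_genes)

    if gene_ids is not None:
        genes = list(gene_ids)
        perm = rng.permutation(n_genes)
        fam = [fam[j] for j in perm]
    else:
        genes = [f"{fam[i]}_{i:04d}" for i in range(n_genes)]
    profiles = np.empty((n_genes, n_segments))
    for i in range(n_genes):
        if fam[i] == "head":
            profiles[i] = base[i] + amp[i] * (1.0 - pos)
        elif fam[i] == "foot":
            profiles[i] = base[i] + amp[i] * pos
        else:
            profiles[i] = base[i]

    cols, meta = [], []
    for si, seg in enumerate(segments):
        for r in range(n_replicates):
            vals = profiles[:, si]
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=n_genes)
            cols.append(vals)
            meta.append((f"{seg}_r{r}", seg))
    values = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=[m[0] for m in meta]
    )
    samples = pd.DataFrame(
        {
            "collection_time": np.nan,
            "condition": "segment",
            "batch": "segments",
            "library_size": np.nan,
            "segment": [m[1] for m in meta],
        },
        index=pd.Index([m[0] for m in meta], name="sample_id"),
    )
    params = pd.DataFrame(
        {"family": fam, "base_log2": base, "amplitude_log2": amp}, index=genes
    )
    return ExpressionMatrix(values, samples, scale="log2"), params


# ---------------------------------------------------------------------------
# batch effect injection
# ---------------------------------------------------------------------------

def inject_batch_effect(
    matrix: ExpressionMatrix,
    gene_shifts: pd.Series,
    batch_labels: pd.Series,
) -> ExpressionMatrix:
    """Apply per-gene log2 shifts to second-batch samples.

    The second batch is the lexicographically later label.  On log2-scale
    matrices the shift is added; on count/normalized scales values are
    multiplied by ``2**shift``.
    """
    if not set(matrix.gene_ids).issubset(set(gene_shifts.index)):
        raise ValueError("gene_shifts do not cover all matrix genes")
    batch_labels = pd.Series(batch_labels).reindex(matrix.sample_ids)
    if batch_labels.isna().any():
        raise ValueError("batch_labels do not cover all samples")
    levels = sorted(batch_labels.unique())
    if len(levels) != 2:
        raise ValueError("expected exactly two batch labels")
    out = matrix.copy()
    mask = (batch_labels == levels[1]).to_numpy()
    shifts = gene_shifts.reindex(matrix.gene_ids).to_numpy()
    block = out.values.to_numpy(dtype=float)
    if matrix.scale == "log2":
        block[:, mask] += shifts[:, None]
    else:
        block[:, mask] *= 2.0 ** shifts[:, None]
    out.values.iloc[:, :] = block
    return out
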