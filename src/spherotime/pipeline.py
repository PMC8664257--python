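"""End-to-end orchestration: simulate -> preprocess -> pseudotime ->
projection -> differential dynamics, with one global seed and a run log.

The configuration is a strict schema: unknown keys are rejected before any
stage runs, stage dependencies are checked up front, and the resolved
configuration is serialized next to the outputs so a run can be reproduced
byte-for-byte from its own directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix
from .dynamics import DifferentialDynamics
from .preprocessing import preprocess
from .projection import fit_segment_basis, select_projection_genes
from .pseudotime import PseudotimeModel
from .synthetic import (
    ExpressionSimConfig,
    generate_expression_timecourse,
    generate_segment_profiles,
)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "pseudotime", "project", "diffdyn")
#: stage -> stages it needs
DEPENDENCIES = {
    "preprocess": ("simulate",),
    "pseudotime": ("preprocess",),
    "project": ("pseudotime",),
    "diffdyn": ("pseudotime",),
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults = study values)."""

    seed: int = 0
    out_dir: str = "spherotime_run"
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate: dict = field(default_factory=dict)  # ExpressionSimConfig fields
    preprocess: dict = field(
        default_factory=lambda: {
            "min_reads": 5_000_000,
            "pseudocount": 8.0,
            "mnn_k": 3,
            "batch_correct": True,
        }
    )
    pseudotime: dict = field(
        default_factory=lambda: {
            "window_span": 7.0,
            "n_iterations": 100,
            "subset_fraction": 0.5,
            "k_window": 4,
            "gamma_window": 1.25,
            "window_alpha": 0.05,
            "n_components": 50,
        }
    )
    project: dict = field(
        default_factory=lambda: {"min_delta": 1.0, "smooth_window": 16}
    )
    diffdyn: dict = field(
        default_factory=lambda: {
            "n_points": 150,
            "k": 8,
            "p_cut": 1e-6,
            "effect_cut": 40.0,
            "top_fraction": 0.10,
            "n_clusters": 5,
        }
    )

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage, needs in DEPENDENCIES.items():
            if self.stages.get(stage, False):
                for dep in needs:
                    if not self.stages.get(dep, False):
                        raise ValueError(
                            f"stage {stage!r} requires stage {dep!r} to be enabled"
                        )
        sim_fields = {f.name for f in dataclasses.fields(ExpressionSimConfig)}
        bad = set(self.simulate) - sim_fields
        if bad:
            raise ValueError(f"unknown simulate option(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        merged = cls()  # defaults
        for key, value in raw.items():
            default = getattr(merged, key)
            if isinstance(default, dict) and isinstance(value, dict):
                if key != "simulate":
                    bad = set(value) - set(default)
                    if bad:
                        raise ValueError(
                            f"unknown key(s) under {key!r}: {sorted(bad)}"
                        )
                default.update(value)
            else:
                setattr(merged, key, value)
        merged.__post_init__()
        return merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def stage_seed(self, stage: str) -> int:
        # one global knob; per-stage seeds are a fixed deterministic spread
        return int((self.seed * 1_000_003 + STAGES.index(stage) * 7919) % 2**31)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, **record):
        record["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages and return the run directory.

    Identical configuration and seed produce identical result tables.  A
    stage failure halts the run; ``status.json`` then names the failed
    stage, and partially written outputs are marked invalid.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved-config.yaml")
    log = _RunLog(out / "run.log")
    status = {"stages_done": [], "valid": True}

    state: dict = {}
    try:
        if config.stages.get("simulate", False):
            _stage_simulate(config, out, state, log)
            status["stages_done"].append("simulate")
        if config.stages.get("preprocess", False):
            _stage_preprocess(config, out, state, log)
            status["stages_done"].append("preprocess")
        if config.stages.get("pseudotime", False):
            _stage_pseudotime(config, out, state, log)
            status["stages_done"].append("pseudotime")
        if config.stages.get("project", False):
            _stage_project(config, out, state, log)
            status["stages_done"].append("project")
        if config.stages.get("diffdyn", False):
            _stage_diffdyn(config, out, state, log)
            status["stages_done"].append("diffdyn")
    except Exception as exc:
        status["valid"] = False
        status["failed_stage"] = _current_stage(status)
        status["error"] = str(exc)
        (out / "status.json").write_text(json.dumps(status, indent=1))
        log.write(event="failed", stage=status["failed_stage"], error=str(exc))
        raise RuntimeError(
            f"pipeline stage {status['failed_stage']!r} failed: {exc}"
        ) from exc

    (out / "status.json").write_text(json.dumps(status, indent=1))
    log.write(event="finished", stages=status["stages_done"])
    return out


def _current_stage(status: dict) -> str:
    done = status["stages_done"]
    for s in STAGES:
        if s not in done:
            return s
    return "unknown"


def _stage_simulate(config, out, state, log):
    sim_cfg = ExpressionSimConfig(
        **{**config.simulate, "seed": config.simulate.get("seed", config.stage_seed("simulate"))}
    )
    matrix, truth = generate_expression_timecourse(sim_cfg)
    segments, seg_params = generate_segment_profiles(
        seed=config.stage_seed("simulate"), gene_ids=list(matrix.gene_ids)
    )
    matrix.to_tsv(out / "counts.tsv")
    truth.to_json(out / "ground_truth.json")
    segments.to_tsv(out / "segments.tsv")
    seg_params.to_csv(out / "segment_gene_params.tsv", sep="\t")
    state.update(matrix=matrix, truth=truth, segments=segments)
    log.write(event="stage", stage="simulate",
              n_genes=matrix.n_genes, n_samples=matrix.n_samples)


def _stage_preprocess(config, out, state, log):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, report = preprocess(state["matrix"], **config.preprocess)
    corrected.to_tsv(out / "log2_corrected.tsv")
    (out / "preprocess_report.json").write_text(json.dumps(report, indent=1))
    state["log2"] = corrected
    log.write(event="stage", stage="preprocess", **{
        k: v for k, v in report.items() if not isinstance(v, list)
    })


def _stage_pseudotime(config, out, state, log):
    logm = state["log2"]
    tables = {}
    for cond in logm.samples["condition"].unique():
        ids = logm.sample_ids[logm.samples["condition"] == cond]
        sub = logm.subset_samples(ids)
        model = PseudotimeModel(sub, **config.pseudotime)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=config.stage_seed("pseudotime"))
        res.to_tsv(out / f"pseudotime_{cond}.tsv")
        (out / f"pseudotime_{cond}_diagnostics.json").write_text(
            json.dumps(res.diagnostics, indent=1, default=str)
        )
        tables[cond] = res
        log.write(event="stage", stage="pseudotime", condition=str(cond),
                  n_windows=len(res.window_estimates))
    state["pseudotime"] = tables


def _stage_project(config, out, state, log):
    logm = state["log2"]
    segments = state["segments"]
    cond = sorted(state["pseudotime"])[0]
    res = state["pseudotime"][cond]
    ids = res.ordered_sample_ids()
    spheroids = logm.subset_samples(ids)
    genes = select_projection_genes(
        segments, spheroids, min_delta=config.project["min_delta"]
    )
    basis = fit_segment_basis(segments, gene_subset=genes)
    scores = basis.project(spheroids, smooth_window=config.project["smooth_window"])
    scores["pseudotime"] = res.pseudotime.loc[ids].to_numpy()
    scores.to_csv(out / "projection_scores.tsv", sep="\t")
    ellipses = {
        label: {
            "center": spec.center.tolist(),
            "axis_lengths": spec.axis_lengths.tolist(),
            "rotation_deg": spec.rotation_deg,
            "level": spec.level,
        }
        for label, spec in basis.group_ellipses(0.9).items()
    }
    (out / "segment_ellipses.json").write_text(json.dumps(ellipses, indent=1))
    state["basis"] = basis
    log.write(event="stage", stage="project", n_basis_genes=len(genes))


def _stage_diffdyn(config, out, state, log):
    logm = state["log2"]
    conds = sorted(state["pseudotime"])
    if len(conds) < 2:
        raise ValueError("differential dynamics needs two conditions")
    ca, cb = conds[0], conds[1]
    ra, rb = state["pseudotime"][ca], state["pseudotime"][cb]
    ids_a, ids_b = list(ra.table.index), list(rb.table.index)
    dd = DifferentialDynamics(
        logm.values[ids_a], ra.pseudotime.loc[ids_a].to_numpy(),
        logm.values[ids_b], rb.pseudotime.loc[ids_b].to_numpy(),
        n_points=config.diffdyn["n_points"],
        k=config.diffdyn["k"],
        p_cut=config.diffdyn["p_cut"],
        effect_cut=config.diffdyn["effect_cut"],
        top_fraction=config.diffdyn["top_fraction"],
        n_clusters=config.diffdyn["n_clusters"],
    )
    res = dd.fit(seed=config.stage_seed("diffdyn"))
    res.to_tsv(out / "differential_table.tsv")
    state["diffdyn"] = res
    log.write(event="stage", stage="diffdyn",
              n_affected=len(res.affected_genes), n_top=len(res.top_genes))
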