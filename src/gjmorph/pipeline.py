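"""End-to-end pipeline: simulate -> detect -> reconstruct -> measure -> compare.

A run is described by a :class:`RunConfig` (a YAML-serialisable record of
every stage's parameters plus one global seed) and leaves behind a
:class:`RunManifest` with a config snapshot, SHA-256 checksums of every
output, the package version and timestamps.  All tables are UTF-8 CSV
with units in the column headers; nested structures are JSON.  The global
seed fans out to per-stage seeds by fixed offsets so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams, detect_beads
from .fixtures import CONTROL_LIKE, PKP2CKO_LIKE, CohortCondition, build_cohort, tiny_fixture
from .morphometrics import (
    cohort_hemiplaque_stats,
    measure,
    plane_rows_frame,
    records_to_frame,
)
from .reconstruction import reconstruct, reconstruction_to_dict
from .stats import compare_groups, plot_boxes, summarize_box
from .synthetic import GroundTruth
from .volume import read_stack, write_stack

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_fixture", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "reconstruct", "measure", "compare")

COMPARED_METRICS = (
    "avg_area_per_length_nm",
    "max_width_nm",
    "hemiplaque_fraction_pct",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    fixture: str = "two_genotype"  # two_genotype | control_like | pkp2cko_like | tiny
    n_plaques_per_group: int = 8
    noise_sd: float = 8.0
    detection: dict = field(default_factory=dict)  # DetectionParams fields
    reconstruction: dict = field(
        default_factory=lambda: {"link_distance_nm": 150.0, "min_beads": 6}
    )
    morphometrics: dict = field(default_factory=dict)  # measure_plaque kwargs
    grouping: str = "pooled"  # pooled | per_ventricle | both
    plot: bool = True  # emit box-and-whisker figures with the comparisons
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class RunManifest:
    """Record of one completed run."""

    config: dict
    version: str
    started: str
    finished: str
    checksums: dict[str, str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _conditions_for(config: RunConfig) -> list[CohortCondition]:
    if config.fixture == "two_genotype":
        return [CONTROL_LIKE, PKP2CKO_LIKE]
    if config.fixture == "control_like":
        return [CONTROL_LIKE]
    if config.fixture == "pkp2cko_like":
        return [PKP2CKO_LIKE]
    raise PipelineError(f"unknown fixture '{config.fixture}'")


def _stage_seed(config: RunConfig, stage: str) -> int:
    return int(config.seed) + 10_000 * STAGES.index(stage)


def _stack_paths(outdir: Path) -> list[Path]:
    return sorted((outdir / "stacks").glob("*.tif"))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest.

    Each stage consumes the previous stage's standard outputs from disk,
    so stages can be re-run individually.  A missing input aborts the run
    with the failing stage named; partial outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs: list[Path] = []

    if config.stages.get("simulate"):
        outputs += _run_simulate(config, outdir)
    if config.stages.get("detect"):
        if not _stack_paths(outdir):
            raise PipelineError("stage 'detect': no stacks found under stacks/")
        outputs += _run_detect(config, outdir)
    if config.stages.get("reconstruct"):
        if not (outdir / "detections.csv").exists():
            raise PipelineError("stage 'reconstruct': missing input detections.csv")
        outputs += _run_reconstruct(config, outdir)
    if config.stages.get("measure"):
        if not (outdir / "detections.csv").exists():
            raise PipelineError("stage 'measure': missing input detections.csv")
        outputs += _run_measure(config, outdir)
    if config.stages.get("compare"):
        if not (outdir / "per_plaque.csv").exists():
            raise PipelineError("stage 'compare': missing input per_plaque.csv")
        outputs += _run_compare(config, outdir)

    config_path = config.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        checksums={
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs + [config_path]))
        },
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    seed = _stage_seed(config, "simulate")
    outputs = []
    if config.fixture == "tiny":
        stack, truth = tiny_fixture(seed=seed)
        rois = [(stack, truth)]
    else:
        rois = []
        for g_i, condition in enumerate(_conditions_for(config)):
            rois += build_cohort(
                condition, n_plaques=config.n_plaques_per_group,
                seed=seed + 97 * g_i, render=True,
            )
    for i, (stack, truth) in enumerate(rois):
        name = f"{truth.labels.get('genotype', 'stack')}_roi{truth.labels.get('roi', i)}"
        outputs.append(write_stack(stack, outdir / "stacks" / f"{name}.tif"))
        outputs.append(Path(str(outputs[-1])).with_suffix(".meta.json"))
        outputs.append(truth.to_json(outdir / "truth" / f"{name}.json"))
        outputs.append(truth.write_bead_table(outdir / "truth" / f"{name}_beads.csv"))
    logger.info("simulate: wrote %d ROI stack(s)", len(rois))
    return outputs


def _run_detect(config: RunConfig, outdir: Path) -> list[Path]:
    params = DetectionParams(**{
        k: tuple(v) if k == "diameter_range_nm" else v
        for k, v in config.detection.items()
    })
    frames = []
    for path in _stack_paths(outdir):
        stack = read_stack(path)
        det = detect_beads(stack, params)
        det.insert(0, "stack_id", path.stem)
        frames.append(det)
    out = pd.concat(frames, ignore_index=True)
    path = outdir / "detections.csv"
    out.to_csv(path, index=False)
    logger.info("detect: %d detections in %d stack(s)", len(out), len(frames))
    return [path]


def _truth_labels(outdir: Path, stack_id: str) -> dict:
    tpath = outdir / "truth" / f"{stack_id}.json"
    if tpath.exists():
        labels = GroundTruth.from_json(tpath).labels
        return {k: labels.get(k) for k in ("genotype", "ventricle", "roi")}
    return {"genotype": None, "ventricle": None, "roi": None}


def _write_qc_overlay(stack, recons, path: Path) -> None:
    """One slice-overlay figure per stack: detections and side polylines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = stack.geometry.n_slices // 2
    g = stack.geometry
    fig, ax = plt.subplots(figsize=(7, 7 * g.n_rows / g.n_cols))
    ax.imshow(
        stack.intensities[k], cmap="gray", origin="upper",
        extent=(0, g.width_nm, g.height_nm, 0),
    )
    for r in recons:
        for p in r.profiles:
            if p.slice != k:
                continue
            det = p.assignments
            ax.scatter(det.x_nm, det.y_nm, s=4, c="yellow", linewidths=0)
            for side, color in (("A", "cyan"), ("B", "magenta")):
                poly = p.sides.get(side)
                if poly is not None:
                    ax.plot(poly.x_nm, poly.y_nm, color=color, lw=0.6)
    ax.set_title(f"{path.stem} (slice {k})", fontsize=8)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)


def _run_reconstruct(config: RunConfig, outdir: Path) -> list[Path]:
    detections = pd.read_csv(outdir / "detections.csv")
    payload = {"stacks": {}}
    for stack_id, det in detections.groupby("stack_id"):
        recons = reconstruct(det.reset_index(drop=True), **config.reconstruction)
        payload["stacks"][str(stack_id)] = reconstruction_to_dict(recons)
        if config.plot:
            tif = outdir / "stacks" / f"{stack_id}.tif"
            if tif.exists():
                qc_dir = outdir / "qc"
                qc_dir.mkdir(exist_ok=True)
                _write_qc_overlay(read_stack(tif), recons, qc_dir / f"{stack_id}.png")
    path = outdir / "reconstruction.json"
    path.write_text(json.dumps(payload))
    return [path]


def _run_measure(config: RunConfig, outdir: Path) -> list[Path]:
    detections = pd.read_csv(outdir / "detections.csv")
    all_records = []
    next_id = 0
    for stack_id, det in detections.groupby("stack_id"):
        labels = {**_truth_labels(outdir, str(stack_id)), "stack_id": str(stack_id)}
        recons = reconstruct(det.reset_index(drop=True), **config.reconstruction)
        records = measure(recons, labels=labels, **config.morphometrics)
        for r in records:
            r.plaque_id = next_id
            next_id += 1
        all_records += records
    per_plaque = records_to_frame(all_records)
    per_plane = plane_rows_frame(all_records)
    p1 = outdir / "per_plaque.csv"
    p2 = outdir / "per_plane.csv"
    per_plaque.to_csv(p1, index=False)
    per_plane.to_csv(p2, index=False)
    logger.info("measure: %d plaque(s), %d plane row(s)", len(per_plaque), len(per_plane))
    return [p1, p2]


def _run_compare(config: RunConfig, outdir: Path) -> list[Path]:
    per_plaque = pd.read_csv(outdir / "per_plaque.csv")
    genotypes = sorted(per_plaque.genotype.dropna().unique())
    comparisons = []
    boxes = []

    def compare_subset(sub: pd.DataFrame, scope: str):
        if len(genotypes) != 2:
            return
        a = sub[sub.genotype == genotypes[0]]
        b = sub[sub.genotype == genotypes[1]]
        for metric in COMPARED_METRICS:
            if len(a) < 3 or len(b) < 3:
                continue
            cmp = compare_groups(
                a[metric], b[metric], metric=metric,
                labels=(str(genotypes[0]), str(genotypes[1])),
            )
            comparisons.append({"scope": scope, **cmp.to_dict()})
            for label, vals in ((genotypes[0], a[metric]), (genotypes[1], b[metric])):
                bx = summarize_box(vals)
                boxes.append(
                    {"scope": scope, "metric": metric, "group": label,
                     "min": bx.min, "q1": bx.q1, "median": bx.median,
                     "q3": bx.q3, "max": bx.max}
                )
            if config.plot:
                plot_boxes(
                    {str(g): sub[sub.genotype == g][metric].to_numpy()
                     for g in genotypes},
                    metric,
                    outdir / f"box_{scope}_{metric}.png",
                )

    if config.grouping in ("pooled", "both"):
        compare_subset(per_plaque, "pooled")
    if config.grouping in ("per_ventricle", "both"):
        for v, sub in per_plaque.groupby("ventricle"):
            compare_subset(sub, f"ventricle_{v}")

    cmp_df = pd.DataFrame(comparisons)
    hemi = cohort_hemiplaque_stats(
        per_plaque,
        group_cols=("genotype", "ventricle") if config.grouping != "pooled" else ("genotype",),
    )
    p1 = outdir / "comparisons.csv"
    p2 = outdir / "comparisons.json"
    p3 = outdir / "hemiplaque_group_stats.csv"
    p4 = outdir / "box_summaries.csv"
    cmp_df.to_csv(p1, index=False)
    p2.write_text(json.dumps(
        {"n_comparisons": len(comparisons), "comparisons": comparisons}, indent=2,
        default=float,
    ))
    hemi.to_csv(p3, index=False)
    pd.DataFrame(boxes).to_csv(p4, index=False)
    return [p1, p2, p3, p4]


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> RunConfig:
    """Write a ready-to-run fixture config (and its data) to ``outdir``.

    ``tiny`` is a single short plaque for smoke tests; ``control_like``
    and ``pkp2cko_like`` are single-genotype cohorts; ``two_genotype`` is
    the default paired-cohort fixture.
    """
    if name not in ("tiny", "control_like", "pkp2cko_like", "two_genotype"):
        raise ValueError(f"unknown fixture '{name}'")
    config = RunConfig(outdir=str(outdir), seed=seed, fixture=name)
    if name == "tiny":
        config.n_plaques_per_group = 1
    config.to_yaml(Path(outdir) / "config.yaml")
    run_pipeline(
        RunConfig(**{**asdict(config), "stages": {"simulate": True}})
    )
    return config
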