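"""End-to-end orchestration: volume -> masks -> graph -> heatmap -> scores.

Configuration lives in one YAML file with per-module blocks; every default the
clinical literature does not constrain is recorded in the run manifest so a run
is auditable.  Identical configuration and seed give byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import ModelParams
from .errors import LungmetError, PipelineError
from .evaluation import (
    cohort_summary,
    default_zeta,
    dice,
    hard_score,
    localization_percentiles,
    metastasis_truth_mask,
    soft_score,
)
from .heatmap import GridSpec, generate_heatmap
from .io import VolumeImage, read_mask, read_volume, write_graph_json, write_mask, write_volume
from .phantom import PhantomSpec, generate_phantom
from .segmentation import SegmentationParams, TumorSpec, detect_primary_tumor, segment_lungs
from .vesselgraph import GraphBuildParams, build_graph, detect_vessels, max_radius_spanning_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    output_dir: Path
    input_volume: Path | None = None
    truth_mask: Path | None = None
    phantom: PhantomSpec | None = None
    manual_tumor: TumorSpec | None = None
    graph_params: GraphBuildParams = field(default_factory=GraphBuildParams)
    model_params: ModelParams = field(default_factory=ModelParams)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    grid: GridSpec = field(default_factory=GridSpec)
    zeta: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.input_volume is None and self.phantom is None:
            raise ValueError("config needs either an input volume or a phantom block")
        if self.input_volume is not None and not Path(self.input_volume).exists():
            raise ValueError(f"input volume does not exist: {self.input_volume}")
        if self.truth_mask is not None and not Path(self.truth_mask).exists():
            raise ValueError(f"truth mask does not exist: {self.truth_mask}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        kw: dict = {}
        kw["output_dir"] = base / raw.get("output_dir", "lungmet-out")
        if "input_volume" in raw:
            kw["input_volume"] = base / raw["input_volume"]
        if "truth_mask" in raw:
            kw["truth_mask"] = base / raw["truth_mask"]
        if "phantom" in raw:
            pk = dict(raw["phantom"] or {})
            if "tumor" in pk:
                pk["tumor"] = TumorSpec(**pk["tumor"])
            kw["phantom"] = PhantomSpec(**pk)
        if "manual_tumor" in raw:
            kw["manual_tumor"] = TumorSpec(**raw["manual_tumor"])
        if "graph" in raw:
            kw["graph_params"] = GraphBuildParams(**raw["graph"])
        if "biophysics" in raw:
            kw["model_params"] = ModelParams(**raw["biophysics"])
        if "segmentation" in raw:
            kw["seg_params"] = SegmentationParams(**raw["segmentation"])
        if "grid" in raw:
            kw["grid"] = GridSpec(tuple(raw["grid"].get("alpha", (4, 4, 4))))
        if "zeta" in raw:
            kw["zeta"] = float(raw["zeta"])
        kw["seed"] = int(raw.get("seed", 0))
        return cls(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute segmentation -> vessel graph -> heatmap (-> scoring).

    Returns the output manifest (also written as ``manifest.json``): every
    artifact with its SHA-256, the parameters used, and summary numbers.  On a
    stage failure a partial manifest is written and PipelineError names the
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "lungmet", "version": __version__},
        "seed": config.seed,
        "parameters": {
            "graph": vars(config.graph_params),
            "biophysics": config.model_params.as_dict(),
            "grid": {"alpha": list(config.grid.alpha)},
            "zeta": config.zeta,
        },
        "outputs": {},
        "summary": {},
    }

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(stage, str(exc)) from exc

    truth = None
    try:
        if config.phantom is not None:
            spec = config.phantom
            if spec.seed != config.seed:
                spec = PhantomSpec(**{**vars(spec), "seed": config.seed})
            volume, truth = generate_phantom(spec)
            write_volume(volume, out / "input.nii.gz")
            record("input_volume", out / "input.nii.gz")
            write_mask(truth.lung_mask, volume.spacing, out / "truth_lung.nii.gz")
            record("truth_lung", out / "truth_lung.nii.gz")
            write_mask(truth.metastasis_mask, volume.spacing, out / "truth_mets.nii.gz")
            record("truth_mets", out / "truth_mets.nii.gz")
        else:
            volume = read_volume(config.input_volume)
    except LungmetError as exc:
        fail("input", exc)

    try:
        tumor = detect_primary_tumor(volume, manual=config.manual_tumor)
        manifest["summary"]["tumor"] = {
            "location_mm": [float(v) for v in tumor.location],
            "radius_mm": float(tumor.size),
        }
    except LungmetError as exc:
        fail("tumor", exc)

    try:
        lung = segment_lungs(volume, tumor=tumor, params=config.seg_params)
        write_mask(lung.mask, volume.spacing, out / "lung_mask.nii.gz")
        record("lung_mask", out / "lung_mask.nii.gz")
        if truth is not None:
            manifest["summary"]["lung_dice"] = dice(lung.mask, truth.lung_mask)
    except LungmetError as exc:
        fail("segmentation", exc)

    try:
        segments = detect_vessels(volume, lung)
        if not segments:
            raise LungmetError("no vessels detected")
        graph = build_graph(segments, config.graph_params)
        tree = max_radius_spanning_tree(graph)
        write_graph_json(tree, out / "vessel_tree.json")
        record("vessel_tree", out / "vessel_tree.json")
        manifest["summary"]["n_vessels"] = len(segments)
        manifest["summary"]["graph_rounds"] = graph.rounds
        manifest["summary"]["final_R"] = graph.final_R
    except LungmetError as exc:
        fail("vesselgraph", exc)

    try:
        hm = generate_heatmap(volume, tumor, lung, tree, config.grid, config.model_params)
        write_volume(VolumeImage(hm.values, volume.spacing), out / "heatmap.nii.gz")
        record("heatmap", out / "heatmap.nii.gz")
        pts = hm.grid_points
        vals = hm.values[tuple(pts.T)]
        pd.DataFrame(
            {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "probability": vals}
        ).to_csv(out / "heatmap_points.csv", index=False)
        record("heatmap_points", out / "heatmap_points.csv")
        manifest["summary"]["heatmap_normalized"] = hm.normalized
    except (LungmetError, ValueError) as exc:
        fail("heatmap", exc)

    try:
        truth_mets = None
        if truth is not None:
            truth_mets = metastasis_truth_mask(truth.metastasis_mask)
        elif config.truth_mask is not None:
            truth_mets = metastasis_truth_mask(read_mask(config.truth_mask))
        if truth_mets is not None:
            zeta = config.zeta if config.zeta is not None else default_zeta(len(hm.grid_points))
            soft = soft_score(truth_mets, hm.values)
            hard = hard_score(truth_mets, hm.values, zeta)
            pct = localization_percentiles(hm, truth_mets)
            manifest["summary"]["scores"] = {
                "soft": soft,
                "hard": hard,
                "zeta": zeta,
                "mean_localization_percentile": float(pct.mean()) if pct.size else None,
            }
    except (LungmetError, ValueError) as exc:
        fail("scoring", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def score_cohort(results: list[dict]):
    """Cohort MEAN +/- STD report from per-run manifests (needs 'scores')."""
    pairs = [
        (m["summary"]["scores"]["soft"], m["summary"]["scores"]["hard"])
        for m in results
        if "scores" in m.get("summary", {})
    ]
    return cohort_summary(pairs)
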