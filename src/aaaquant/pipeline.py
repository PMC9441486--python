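"""Reproducible orchestration of the full analysis pipeline.

A :class:`RunConfig` (YAML-serializable) describes one run: synthetic
slide specs, tiling, network/training settings, detection parameters
per stain, and seeds.  :func:`run_pipeline` executes the requested
stages in dependency order — synthesize -> tile -> train -> segment ->
masks -> quantify — and writes a JSON run manifest recording the
package version, seeds, and SHA-256 hashes of every artifact, so a run
can be audited and re-executed.  Completed stages are skipped unless
forced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import fit_normalization, NormalizationStats
from .classes import DEFAULT_MICRONS_PER_PX
from .network import NetworkConfig, UNet, build_unet
from .quantify import CD8_PARAMS, detect_cells, write_zone_report, zone_report
from .synthetic import SlideSpec, ZoneGeometry, generate_ihc_slide, generate_weigert_slide, write_slide_bundle
from .tiling import AnnotationMap, filter_mosaic, make_mosaic, stitch_predictions
from .training import TrainConfig, predict_tiles, train
from .zonemap import apply_masks, masks_from_prediction
from . import raster_io
from .evaluation import class_report, confusion

STAGES = ("synthesize", "tile", "train", "segment", "masks", "quantify")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML round-trippable."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic study conditions
    slide_px: int = 512
    microns_per_px: float = DEFAULT_MICRONS_PER_PX
    n_train_slides: int = 3
    n_val_slides: int = 1
    fiber_fractions: dict = field(
        default_factory=lambda: {
            "zone1": {"elastin": 0.25, "collagen": 0.30},
            "zone2": {"elastin": 0.05, "collagen": 0.40},
        }
    )
    cells_per_zone: dict = field(default_factory=lambda: {"zone1": 40, "zone2": 25})
    positive_fraction: dict = field(default_factory=lambda: {"zone1": 0.4, "zone2": 0.1})
    # tiling / network / training (test-scale defaults)
    tile_size: int = 128
    stride: int = 64
    depth: int = 2
    base_filters: int = 8
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 8
    qc_gate: float = 0.8

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _slide_specs(cfg: RunConfig) -> list[SlideSpec]:
    specs = []
    for i in range(cfg.n_train_slides + cfg.n_val_slides):
        specs.append(
            SlideSpec(
                width_px=cfg.slide_px,
                height_px=cfg.slide_px,
                microns_per_px=cfg.microns_per_px,
                zone_geometry=ZoneGeometry(),
                fiber_fractions=cfg.fiber_fractions,
                seed=cfg.seed * 1000 + i,
            )
        )
    return specs


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES,
                 force: bool = False) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() and not force
        else {"version": __version__, "seed": cfg.seed, "stages": {}, "artifacts": {}}
    )
    cfg.to_yaml(out / "config.yaml")

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {"completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
        for key, p in paths.items():
            manifest["artifacts"][f"{stage}/{key}"] = {
                "path": str(p.relative_to(out)),
                "sha256": _sha256(p),
            }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def done(stage: str) -> bool:
        return not force and stage in manifest["stages"]

    specs = _slide_specs(cfg)

    if "synthesize" in stages and not done("synthesize"):
        paths = {}
        for i, spec in enumerate(specs):
            rgb, truth = generate_weigert_slide(spec)
            bundle = write_slide_bundle(out / "slides", spec, rgb, truth, prefix=f"weigert_{i}")
            paths.update({f"weigert_{i}_{k}": v for k, v in bundle.items()})
            ihc, ihc_truth = generate_ihc_slide(spec, cfg.cells_per_zone, cfg.positive_fraction)
            bundle = write_slide_bundle(out / "slides", spec, ihc, ihc_truth, prefix=f"ihc_{i}")
            paths.update({f"ihc_{i}_{k}": v for k, v in bundle.items()})
        record("synthesize", paths)

    if "tile" in stages and not done("tile"):
        _require(out / "slides" / "weigert_0.png", "synthesize")
        from .tiling import write_tile_pairs

        paths = {}
        for i in range(len(specs)):
            slide = raster_io.load_rgb(out / "slides" / f"weigert_{i}.png")
            ann = AnnotationMap.load(out / "slides" / f"weigert_{i}_annotation.png",
                                     cfg.microns_per_px)
            records = filter_mosaic(
                make_mosaic(slide, ann, cfg.tile_size, cfg.stride,
                            scaling=2 ** cfg.depth, slide_id=f"weigert_{i}")
            )
            write_tile_pairs(records, out / "tiles" / f"slide_{i}")
            paths[f"manifest_{i}"] = out / "tiles" / f"slide_{i}" / "manifest.csv"
        record("tile", paths)

    if "train" in stages and not done("train"):
        _require(out / "tiles" / "slide_0" / "manifest.csv", "tile")
        train_recs, val_recs = [], []
        for i in range(len(specs)):
            slide = raster_io.load_rgb(out / "slides" / f"weigert_{i}.png")
            ann = AnnotationMap.load(out / "slides" / f"weigert_{i}_annotation.png",
                                     cfg.microns_per_px)
            recs = filter_mosaic(
                make_mosaic(slide, ann, cfg.tile_size, cfg.stride,
                            scaling=2 ** cfg.depth, slide_id=f"weigert_{i}")
            )
            (train_recs if i < cfg.n_train_slides else val_recs).extend(recs)
        stats = fit_normalization((r.input_tile for r in train_recs), "training tiles")
        stats.to_yaml(out / "normalization.yaml")
        net_cfg = NetworkConfig(depth=cfg.depth, base_filters=cfg.base_filters,
                                tile_size=cfg.tile_size)
        model = build_unet(net_cfg, np.random.default_rng(cfg.seed))
        t_cfg = TrainConfig(epochs=cfg.epochs, learning_rate=cfg.learning_rate,
                            batch_size=cfg.batch_size, seed=cfg.seed)
        state = train(model, train_recs, val_recs, t_cfg, stats,
                      checkpoint_path=out / "model.npz")
        state.to_csv(out / "training_log.csv")
        record("train", {"model": out / "model.npz", "log": out / "training_log.csv",
                         "normalization": out / "normalization.yaml"})

    if "segment" in stages and not done("segment"):
        _require(out / "model.npz", "train")
        model = UNet.load(out / "model.npz")
        stats = NormalizationStats.from_yaml(out / "normalization.yaml")
        paths = {}
        val_idx = cfg.n_train_slides  # first validation slide
        slide = raster_io.load_rgb(out / "slides" / f"weigert_{val_idx}.png")
        ann = AnnotationMap.load(out / "slides" / f"weigert_{val_idx}_annotation.png",
                                 cfg.microns_per_px)
        recs = make_mosaic(slide, ann, cfg.tile_size, cfg.stride,
                           scaling=2 ** cfg.depth)
        probs = predict_tiles(model, [(r.origin, r.input_tile) for r in recs], stats)
        pred = stitch_predictions(probs, ann.shape, microns_per_px=cfg.microns_per_px)
        pred.save(out / "prediction.png")
        report = class_report(confusion(pred, ann))
        report.to_csv(out / "classification_report.csv")
        paths["prediction"] = out / "prediction.png"
        paths["report"] = out / "classification_report.csv"
        record("segment", paths)

    if "masks" in stages and not done("masks"):
        _require(out / "prediction.png", "segment")
        pred = AnnotationMap.load(out / "prediction.png", cfg.microns_per_px)
        masks = masks_from_prediction(pred)
        paths = masks.save(out / "masks")
        record("masks", paths)

    if "quantify" in stages and not done("quantify"):
        _require(out / "masks" / "mask_combined.png", "masks")
        from .zonemap import ZoneMaskSet

        masks = ZoneMaskSet.load(out / "masks" / "mask_combined.png", cfg.microns_per_px)
        val_idx = cfg.n_train_slides
        ihc = raster_io.load_rgb(out / "slides" / f"ihc_{val_idx}.png")
        qc, masks = apply_masks(masks, ihc, gate=cfg.qc_gate)
        detections = detect_cells(ihc, CD8_PARAMS, microns_per_px=cfg.microns_per_px)
        rows = zone_report(detections, masks)
        write_zone_report(rows, out / "cell_report.csv")
        (out / "qc.json").write_text(json.dumps({"score": qc.score, "passed": qc.passed,
                                                 "reason": qc.reason}))
        record("quantify", {"cells": out / "cell_report.csv", "qc": out / "qc.json"})

    return manifest


def _require(path: Path, stage: str) -> None:
    if not path.exists():
        raise PipelineError(f"missing artifact {path}; run the '{stage}' stage first")
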