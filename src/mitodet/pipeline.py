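"""End-to-end orchestration: simulate -> normalize -> extract-features ->
select-features -> train -> evaluate.

Each enabled stage writes its artifacts into the run directory together
with a provenance manifest (config echo, package version, derived stage
seeds) sufficient to re-execute the run. Any stage failure halts with the
failing stage named. Tile-level labels (does the tile contain a mitotic
figure?) drive the feature-selection stage and the final confusion-based
metric report; the trained detector is scored at object level as well.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cdl import (
    build_cdl, detection_f1, postprocess_detections, predict_segmentation,
    train as train_network,
)
from .config import RunConfig, save_config, stage_seed
from .features import default_feature_registry, extract_feature_vector, write_feature_table
from .metrics import confusion_from_labels, metric_suite
from .selection import hjwoa_run, selection_report
from .stain import estimate_stain_profile, normalize_to_reference, pick_reference
from .synthetic import gen_he_tile
from .tile import write_tile

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the consolidated report.

    Artifacts land under ``config.out_dir``: normalized tiles and masks as
    PNG, the feature table as CSV, selection and metric reports as JSON,
    and ``provenance.json`` with everything needed to re-execute.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    t_start = time.time()
    report: dict = {"stages": {}, "package_version": __version__}
    save_config(config, out / "config.yaml")

    tiles = {}
    enabled = set(config.stages)
    timings = {}

    def _stage(name):
        if name not in enabled:
            return False
        timings[name] = time.time()
        logger.info(json.dumps({"event": "stage_start", "stage": name}))
        return True

    def _done(name):
        timings[name] = time.time() - timings[name]
        logger.info(json.dumps({"event": "stage_done", "stage": name,
                                "seconds": timings[name]}))

    # ---- simulate --------------------------------------------------------
    if _stage("simulate"):
        try:
            seed0 = stage_seed(config.seed, "simulate")
            rng = np.random.default_rng(seed0)
            counts = {"train": config.n_train_tiles, "val": config.n_val_tiles,
                      "test": config.n_test_tiles}
            for split, n in counts.items():
                tiles[split] = []
                for _ in range(n):
                    params = dataclasses.replace(
                        config.tile,
                        n_mitotic=int(rng.integers(0, config.tile.n_mitotic + 1)),
                        seed=int(rng.integers(2 ** 31)),
                    )
                    tile = gen_he_tile(params)
                    tile.split_tag = split
                    tiles[split].append(tile)
            report["stages"]["simulate"] = {
                k: len(v) for k, v in tiles.items()
            }
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        _done("simulate")
    elif {"normalize", "extract_features", "train", "evaluate"} & enabled:
        raise PipelineError(
            "simulate",
            "downstream stages need tiles; enable 'simulate' first",
        )

    # ---- normalize -------------------------------------------------------
    if _stage("normalize"):
        try:
            reference = pick_reference(tiles["train"])
            profile = estimate_stain_profile(reference)
            norm_dir = out / "normalized"
            norm_dir.mkdir(exist_ok=True)
            for split in tiles:
                tiles[split] = [
                    normalize_to_reference(t, profile) for t in tiles[split]
                ]
            for t in tiles["train"][:4]:  # sample artifacts
                write_tile(t, norm_dir / f"{t.id}.png",
                           mask_path=norm_dir / f"{t.id}_mask.png")
            report["stages"]["normalize"] = {"reference": reference.id}
        except Exception as exc:
            raise PipelineError("normalize", str(exc)) from exc
        _done("normalize")

    # ---- extract features ------------------------------------------------
    registry = default_feature_registry()
    vectors = None
    if _stage("extract_features"):
        try:
            vectors = {}
            for split in tiles:
                vectors[split] = [
                    extract_feature_vector(
                        t, registry,
                        label=int(bool(t.mask is not None and t.mask.any())),
                    )
                    for t in tiles[split]
                ]
            write_feature_table(
                out / "features.csv",
                [fv for split in vectors.values() for fv in split],
            )
            report["stages"]["extract_features"] = {
                "n_vectors": sum(len(v) for v in vectors.values()),
                "n_slots": len(registry),
            }
        except Exception as exc:
            raise PipelineError("extract_features", str(exc)) from exc
        _done("extract_features")

    # ---- select features -------------------------------------------------
    if _stage("select_features"):
        try:
            if vectors is None:
                raise PipelineError(
                    "select_features",
                    "no feature table; run 'extract_features' first",
                )
            fvs = vectors["train"] + vectors["val"]
            X = np.stack([fv.values for fv in fvs])
            y = np.array([fv.label for fv in fvs])
            hjwoa_cfg = dataclasses.replace(
                config.hjwoa, seed=stage_seed(config.seed, "select_features")
            )
            result = hjwoa_run(X, y, registry, hjwoa_cfg)
            result.to_json(out / "selection.json")
            report["stages"]["select_features"] = selection_report(result, registry)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("select_features", str(exc)) from exc
        _done("select_features")
    else:
        report["stages"]["select_features"] = "skipped"

    # ---- train -----------------------------------------------------------
    net = None
    if _stage("train"):
        try:
            cdl_cfg = dataclasses.replace(
                config.cdl,
                seed=stage_seed(config.seed, "train"),
                input_side=config.tile.side,
            )
            net = build_cdl(cdl_cfg)
            state = train_network(net, tiles["train"], tiles["val"], cdl_cfg)
            report["stages"]["train"] = {
                "epochs": state.epoch,
                "best_val_loss": state.best_val_loss,
                "stop_reason": state.stop_reason,
            }
            with open(out / "train_history.json", "w") as fh:
                json.dump(state.history, fh, indent=2)
        except Exception as exc:
            raise PipelineError("train", str(exc)) from exc
        _done("train")

    # ---- evaluate --------------------------------------------------------
    if _stage("evaluate"):
        try:
            if net is None:
                raise PipelineError(
                    "evaluate", "no trained network; run 'train' first"
                )
            pred_labels, true_labels, det_pairs = [], [], []
            for t in tiles["test"]:
                prob = predict_segmentation(net, t)
                dets = postprocess_detections(prob)
                pred_labels.append(int(bool(dets)))
                true_labels.append(int(bool(t.mask is not None and t.mask.any())))
                det_pairs.append((dets, t.mask))
            counts = confusion_from_labels(pred_labels, true_labels)
            suite = metric_suite(counts)
            payload = suite.to_dict()
            payload["object_detection_f1"] = detection_f1(det_pairs)
            payload["confusion"] = dataclasses.asdict(counts)
            if "select_features" not in enabled:
                payload["selection"] = "skipped"
            with open(out / "report.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            report["stages"]["evaluate"] = payload
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc
        _done("evaluate")

    report["seconds"] = {k: round(v, 3) for k, v in timings.items()}
    provenance = {
        "config": config.to_dict(),
        "package_version": __version__,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "total_seconds": round(time.time() - t_start, 3),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    with open(out / "pipeline_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
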