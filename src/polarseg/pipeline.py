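"""End-to-end pipeline: synth -> (augment) -> train -> predict -> evaluate.

All stage artifacts (manifests, checkpoints, predictions, the evaluation
report) land under one run directory, and every source of randomness is
derived deterministically from a single global seed, so a rerun with the
same configuration reproduces the report's per-sample correctness flags
exactly on the same platform.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import augment_manifest
from .detect import NMSConfig, detect
from .evaluate import DEFAULT_TOL_PX, EvalReport, evaluate, truth_from_mask
from .io import read_image, read_mask
from .model import NetworkConfig, SegmentationNetwork
from .synth import generate_dataset
from .train import TrainConfig, train

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("polarseg")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str | Path = "run"
    seed: int = 0
    # data
    n_train_positive: int = 300
    n_train_negative: int = 100
    n_test_positive: int = 75
    n_test_negative: int = 25
    difficulty: str = "mixed"
    size: tuple[int, int] = (128, 128)
    augment: bool = False
    # model / training
    base_channels: int = 16
    up_mode: str = "transposed"
    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 2e-3
    lr_schedule: str = "cosine"
    beta: float = 0.5
    validation_fraction: float = 0.2
    # detection / evaluation
    prob_threshold: float = 0.5
    support_threshold: float = 0.1
    min_area: int = 30
    connectivity: int = 8
    tol: float = DEFAULT_TOL_PX

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "size" in data:
            data["size"] = tuple(data["size"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["out_dir"] = str(data["out_dir"])
        data["size"] = list(data["size"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def stage_seeds(self) -> dict[str, int]:
        """Deterministically derive one sub-seed per stage from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["train_data", "test_data", "augment", "init", "train"]
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def run_pipeline(cfg: PipelineConfig) -> EvalReport:
    """Execute all stages and return the held-out evaluation report."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    seeds = cfg.stage_seeds()
    t0 = time.time()

    def stage(name):
        log.info("[%7.1fs] stage %s", time.time() - t0, name)

    try:
        stage("synth:train")
        train_manifest = generate_dataset(
            cfg.n_train_positive, cfg.n_train_negative, cfg.difficulty,
            run_dir / "train_data", seeds["train_data"], size=cfg.size,
        )
        stage("synth:test")
        test_manifest = generate_dataset(
            cfg.n_test_positive, cfg.n_test_negative, cfg.difficulty,
            run_dir / "test_data", seeds["test_data"], size=cfg.size,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'synth' failed: {e}") from e

    if cfg.augment:
        try:
            stage("augment")
            train_manifest = augment_manifest(train_manifest, run_dir / "augmented", seeds["augment"])
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'augment' failed: {e}") from e

    try:
        stage("train")
        net = SegmentationNetwork(NetworkConfig(cfg.base_channels, cfg.up_mode, seed=seeds["init"]))
        tcfg = TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            lr_schedule=cfg.lr_schedule,
            beta=cfg.beta,
            seed=seeds["train"],
            validation_fraction=cfg.validation_fraction,
            checkpoint_dir=run_dir / "checkpoints",
        )
        net, history = train(net, train_manifest, tcfg)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'train' failed: {e}") from e

    try:
        stage("predict")
        nms = NMSConfig(cfg.prob_threshold, cfg.support_threshold, cfg.min_area, cfg.connectivity)
        predictions, truths, names = [], [], []
        for entry in test_manifest.entries:
            img = read_image(test_manifest.image_path(entry))
            mask = read_mask(test_manifest.mask_path(entry))
            predictions.append(detect(net, img, nms))
            truths.append(truth_from_mask(mask))
            names.append(entry.image)
        pred_df = pd.DataFrame(
            {
                "image": names,
                "present": [p.present for p in predictions],
                "row": [p.centroid[0] if p.present else np.nan for p in predictions],
                "col": [p.centroid[1] if p.present else np.nan for p in predictions],
                "confidence": [p.confidence for p in predictions],
                "area": [p.area for p in predictions],
            }
        )
        pred_df.to_csv(run_dir / "predictions.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'predict' failed: {e}") from e

    try:
        stage("evaluate")
        report = evaluate(predictions, truths, tol=cfg.tol)
        report.records.to_csv(run_dir / "report.csv", index=False)
        (run_dir / "report.json").write_text(
            json.dumps(
                {
                    "n_total": report.n_total,
                    "n_positive": report.n_positive,
                    "n_negative": report.n_negative,
                    "n_correct": report.n_correct,
                    "accuracy": report.accuracy,
                    "positive_accuracy": report.positive_accuracy,
                    "negative_accuracy": report.negative_accuracy,
                },
                indent=2,
            )
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'evaluate' failed: {e}") from e

    stage("done")
    return report
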