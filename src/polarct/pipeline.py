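"""Run orchestration: config schema, stage execution, provenance.

A ``RunConfig`` composes every module's parameters; ``run_pipeline``
executes a dependency-ordered subset of stages, each stage reading only the
outputs of earlier ones, and records the resolved config, logs and metrics
inside the run directory so any artifact can be regenerated from it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .baselines import TVConfig, extrapolate_and_reconstruct, tv_reconstruct
from .ctsim import FanGeometry, forward_project, truncate_sinogram
from .grids import ImageGrid
from .metrics import evaluate_pairs
from .phantoms import DatasetManifest, PhantomSpec, build_unpaired_dataset
from .train import Checkpoint, TrainConfig, TruncationRemovalModel, remove_artifacts

__all__ = ["RunConfig", "run_pipeline", "STAGES", "ConfigError", "DataError"]

STAGES = ("simulate", "train", "infer", "baseline", "evaluate")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed upstream artifacts (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Composed configuration of the full simulate-train-evaluate pipeline."""

    seed: int = 0
    out_dir: str = "run"
    n_train: int = 200
    n_test: int = 24
    truncation_ratio: float = 0.3
    out_size: int = 64
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(size=64))
    n_views: int = 720
    train: TrainConfig = field(default_factory=TrainConfig)
    baseline_method: str = "tv"
    tv: TVConfig = field(default_factory=TVConfig)
    restrict_fov: bool = True

    def validate(self) -> None:
        if not (0 <= self.truncation_ratio < 1):
            raise ConfigError("truncation_ratio must be in [0, 1)")
        if self.n_train < 1 or self.n_test < 1:
            raise ConfigError("n_train and n_test must be positive")
        if self.out_size < 16:
            raise ConfigError("out_size must be at least 16")
        if self.baseline_method not in ("tv", "extrapolation"):
            raise ConfigError("baseline_method must be 'tv' or 'extrapolation'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = asdict(self.phantom)
        d["train"] = self.train.to_dict()
        d["tv"] = asdict(self.tv)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            ph = dict(d["phantom"])
            ph["body_axes"] = tuple(ph.get("body_axes", (0.9, 0.84)))
            ph["contrast_range"] = tuple(ph.get("contrast_range", (-0.5, 1.0)))
            d["phantom"] = PhantomSpec(**ph)
        if "train" in d:
            d["train"] = TrainConfig.from_dict(d["train"]) if isinstance(d["train"], dict) else d["train"]
        if "tv" in d:
            d["tv"] = TVConfig(**d["tv"]) if isinstance(d["tv"], dict) else d["tv"]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except Exception as exc:  # malformed YAML is a config error
            raise ConfigError(f"cannot parse config file: {exc}") from exc
        return cls.from_dict(payload or {})


def _log(run_dir: Path, record: dict) -> None:
    with open(run_dir / "pipeline.jsonl", "a") as fh:
        fh.write(json.dumps(record) + "\n")


def run_pipeline(cfg: RunConfig, stages) -> Path:
    """Execute the requested pipeline stages in dependency order.

    Stages: ``simulate`` (phantom dataset), ``train`` (fit the network),
    ``infer`` (correct the test images), ``baseline`` (classical
    comparator), ``evaluate`` (metric CSV for whatever estimates exist).
    Raises ``DataError`` when a stage's inputs are missing.
    """
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ConfigError("no known stages requested")
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    data_dir = run_dir / "dataset"

    def manifest_or_fail() -> DatasetManifest:
        if not (data_dir / "manifest.json").exists():
            raise DataError("dataset missing: run the simulate stage first")
        return DatasetManifest.load(data_dir)

    geometry = FanGeometry.default_for(cfg.phantom.size, out_size=cfg.out_size, n_views=cfg.n_views)

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            build_unpaired_dataset(
                cfg.n_train, cfg.n_test, cfg.phantom, geometry,
                ratio=cfg.truncation_ratio, out_dir=data_dir,
                out_size=cfg.out_size, seed=cfg.seed,
            )
        elif stage == "train":
            manifest = manifest_or_fail()
            model = TruncationRemovalModel.from_manifest(manifest, cfg.train)
            results = model.fit(seed=cfg.seed)
            results.save(run_dir / "checkpoint.zip")
        elif stage == "infer":
            manifest = manifest_or_fail()
            ckpt_path = run_dir / "checkpoint.zip"
            if not ckpt_path.exists():
                raise DataError("checkpoint missing: run the train stage first")
            ckpt = Checkpoint.load(ckpt_path)
            est_dir = run_dir / "estimates" / "network"
            est_dir.mkdir(parents=True, exist_ok=True)
            for entry in manifest.by_role("artifact", split="test"):
                corrected = remove_artifacts(manifest.load_image(entry), ckpt)
                corrected.save(est_dir / entry.id)
        elif stage == "baseline":
            manifest = manifest_or_fail()
            est_dir = run_dir / "estimates" / cfg.baseline_method
            est_dir.mkdir(parents=True, exist_ok=True)
            from .phantoms import make_ellipse_phantom

            for entry in manifest.by_role("artifact", split="test"):
                phantom = make_ellipse_phantom(cfg.phantom.with_seed(entry.seed))
                sino = truncate_sinogram(forward_project(phantom, geometry), cfg.truncation_ratio) \
                    if cfg.truncation_ratio > 0 else forward_project(phantom, geometry)
                if cfg.baseline_method == "tv":
                    est = tv_reconstruct(sino, cfg.tv, cfg.out_size)
                else:
                    est = extrapolate_and_reconstruct(sino, cfg.out_size)
                est.save(est_dir / entry.id)
        elif stage == "evaluate":
            manifest = manifest_or_fail()
            est_root = run_dir / "estimates"
            if not est_root.exists() or not any(est_root.iterdir()):
                raise DataError("no estimates present: run infer or baseline first")
            refs = {e.id: e for e in manifest.by_role("reference", split="test")}
            for method_dir in sorted(est_root.iterdir()):
                pairs = []
                for entry in manifest.by_role("artifact", split="test"):
                    est_path = method_dir / entry.id
                    if not est_path.with_suffix(".npy").exists():
                        raise DataError(f"estimate missing for {entry.id} in {method_dir.name}")
                    pairs.append((
                        entry.id,
                        ImageGrid.load(est_path),
                        manifest.load_image(refs[entry.id]),
                    ))
                report = evaluate_pairs(pairs, restrict_fov=cfg.restrict_fov,
                                        metadata={"method": method_dir.name})
                report.to_csv(run_dir / f"metrics_{method_dir.name}.csv")
        _log(run_dir, {"stage": stage, "seconds": round(time.time() - t0, 3),
                       "seed": cfg.seed})
    return run_dir
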