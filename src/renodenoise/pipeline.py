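"""End-to-end orchestration: simulate -> prepare -> train -> evaluate -> stats.

Each stage is idempotent: it checks for its own outputs in the run
directory and skips the work when they already exist (``force`` reruns).
Every run directory carries a manifest with the fully-serialized config,
the seed and a config hash, so any artifact can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import dose, phantom
from .metrics import evaluate_method
from .models import (NetworkConfig, build_discriminator, build_model, denoise,
                     load_checkpoint, save_checkpoint)
from .stats import age_group_summary, pairwise_table
from .study_io import StudyRecord, read_array_study, read_roi_masks, \
    write_array_study, write_roi_masks
from .training import TrainingConfig, train, _stack

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "STAGES"]

log = logging.getLogger("renodenoise.pipeline")

STAGES = ("simulate", "prepare", "train", "evaluate", "stats")
_FAMILIES = ("dncnn", "udncnn", "dudncnn", "attngan")


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible pipeline run needs."""
    n_studies: int = 32
    image_size: int = 64
    n_frames: int = 120
    frame_duration_s: float = 10.0
    dose_fractions: Tuple[float, float] = (1.0, 0.5)
    scheme: str = "alternating"
    split_fractions: Tuple[float, float, float] = (0.67, 0.16, 0.17)
    families: Tuple[str, ...] = ("udncnn",)
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 200
    seed: int = 0
    output_dir: str = "runs/renodenoise"
    age_group_width: int = 3

    def validate(self) -> None:
        if self.n_studies < 3:
            raise ConfigError("need at least 3 studies to form splits")
        if self.image_size < 16 or self.image_size % 16:
            raise ConfigError("image_size must be a multiple of 16 (>= 16)")
        if self.n_frames < 2:
            raise ConfigError("need at least 2 frames")
        for family in self.families:
            if family not in _FAMILIES:
                raise ConfigError(f"unknown model family '{family}'")
        if not (0 < self.dose_fractions[1] <= self.dose_fractions[0] <= 1.0):
            raise ConfigError("dose fractions must satisfy 0 < reduced <= full <= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        try:
            self.training_config()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(batch_size=self.batch_size,
                              learning_rate=self.learning_rate,
                              optimizer=self.optimizer,
                              epochs=self.epochs, seed=self.seed,
                              allow_off_grid=True)

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("dose_fractions", "split_fractions", "families"):
            d[key] = list(d[key])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dose_fractions", "split_fractions", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        config.validate()
        return config

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _study_ages(config: PipelineConfig) -> List[float]:
    # one case per (scaled) age group, covering 0..17 like the source cohort
    n = config.n_studies
    return [float((i * 17) // max(n - 1, 1)) for i in range(n)]


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    manifest = {"config": asdict(config), "seed": config.seed,
                "config_hash": config.config_hash}
    for key in ("dose_fractions", "split_fractions", "families"):
        manifest["config"][key] = list(manifest["config"][key])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.yaml").write_text(config.to_yaml())


def stage_simulate(config: PipelineConfig, outdir: Path, force: bool = False) -> List[StudyRecord]:
    """Generate the synthetic cohort; cached as npz + PNG ROI masks."""
    studies_dir = outdir / "studies"
    studies_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, age in enumerate(_study_ages(config)):
        study_path = studies_dir / f"study_{i:03d}.npz"
        roi_path = studies_dir / f"study_{i:03d}_rois.json"
        spec = phantom.make_phantom_spec(seed=config.seed * 10_000 + i,
                                         patient_age_years=age,
                                         image_size=config.image_size)
        if study_path.exists() and roi_path.exists() and not force:
            record = read_array_study(study_path)
            record.rois = read_roi_masks(roi_path)
            records.append(record)
            continue
        study = phantom.sample_study(spec, count_scale=1.0,
                                     n_frames=config.n_frames,
                                     frame_duration_s=config.frame_duration_s,
                                     study_id=f"study_{i:03d}")
        rois = phantom.ground_truth_rois(spec)
        record = StudyRecord(study=study, rois=rois, source_path=str(study_path))
        write_array_study(record, study_path)
        write_roi_masks(rois, studies_dir, stem=f"study_{i:03d}")
        records.append(record)
    log.info("simulate: %d studies in %s", len(records), studies_dir)
    return records


def stage_prepare(config: PipelineConfig, outdir: Path,
                  records: Sequence[StudyRecord], force: bool = False
                  ) -> List[dose.PairedSample]:
    """Sum frames into 100%/50% pairs, assign splits, write the manifest CSV."""
    dataset_dir = outdir / "dataset"
    dataset_dir.mkdir(parents=True, exist_ok=True)
    pairs, inventory = dose.build_dataset(records, scheme=config.scheme,
                                          fractions=config.dose_fractions)
    assignment = dose.split_dataset(pairs, fractions=config.split_fractions,
                                    seed=config.seed,
                                    group_ids=[p.study_id for p in pairs])
    rows = []
    for pair, split in zip(pairs, assignment):
        pair.split = split
        rows.append({"study_id": pair.study_id,
                     "age": pair.input_image.patient_age_years,
                     "split": split,
                     "count_fraction_input": pair.input_image.count_fraction,
                     "count_fraction_reference": pair.reference_image.count_fraction})
    manifest = pd.DataFrame(rows)
    manifest_path = dataset_dir / "manifest.csv"
    if not manifest_path.exists() or force:
        manifest.to_csv(manifest_path, index=False)
    log.info("prepare: %d pairs (%d images), splits %s", len(pairs), inventory,
             manifest["split"].value_counts().to_dict())
    return pairs


def _split(pairs: Sequence[dose.PairedSample], name: str) -> List[dose.PairedSample]:
    return [p for p in pairs if p.split == name]


def stage_train(config: PipelineConfig, outdir: Path,
                pairs: Sequence[dose.PairedSample], force: bool = False
                ) -> Dict[str, Path]:
    """Train each requested family; checkpoints and loss histories cached."""
    checkpoints = {}
    train_pairs, val_pairs = _split(pairs, "train"), _split(pairs, "val")
    for family in config.families:
        run_dir = outdir / "models" / family
        run_dir.mkdir(parents=True, exist_ok=True)
        ckpt = run_dir / "checkpoint.npz"
        checkpoints[family] = ckpt
        if ckpt.exists() and not force:
            log.info("train[%s]: cached checkpoint found, skipping", family)
            continue
        net_config = NetworkConfig(family=family, seed=config.seed)
        model = build_model(net_config)
        discriminator = build_discriminator(net_config) \
            if family == "attngan" else None
        t_config = config.training_config()
        (run_dir / "config.yaml").write_text(
            net_config.to_yaml() + "\n" + yaml.safe_dump(asdict(t_config)))
        model, history = train(
            model, train_pairs, val_pairs, t_config,
            target_size=config.image_size, discriminator=discriminator,
            log=lambda e, tr, vl: log.info(
                "train[%s] epoch %d: train %.6f val %.6f", family, e, tr, vl))
        save_checkpoint(model, ckpt)
        pd.DataFrame({"epoch": range(len(history.train)),
                      "train_mse": history.train,
                      "val_mse": history.validation}
                     ).to_csv(run_dir / "loss_history.csv", index=False)
    return checkpoints


def stage_evaluate(config: PipelineConfig, outdir: Path,
                   pairs: Sequence[dose.PairedSample],
                   checkpoints: Dict[str, Path], force: bool = False
                   ) -> pd.DataFrame:
    """Denoise the test split and score every method against the baseline."""
    metrics_dir = outdir / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)
    report_path = metrics_dir / "metrics.csv"
    if report_path.exists() and not force:
        return pd.read_csv(report_path)
    test_pairs = _split(pairs, "test")
    xs, ys = _stack(test_pairs, config.image_size)
    rois = [p.rois for p in test_pairs]
    ids = [p.study_id for p in test_pairs]
    ages = [p.input_image.patient_age_years for p in test_pairs]
    denoised = {family: denoise(load_checkpoint(path), xs)
                for family, path in checkpoints.items()}
    report, summary = evaluate_method(denoised, xs, ys, rois,
                                      study_ids=ids, ages=ages)
    report.to_csv(report_path, index=False)
    summary.to_csv(metrics_dir / "summary.csv")
    log.info("evaluate: summary (signed %% change vs noisy baseline)\n%s", summary)
    return report


def stage_stats(config: PipelineConfig, outdir: Path,
                report: pd.DataFrame, force: bool = False) -> Dict[str, pd.DataFrame]:
    """Pairwise p-value tables per metric plus the age-group summary."""
    stats_dir = outdir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    tables = {}
    methods = list(report["method"].unique())
    for metric in ("snr_right", "snr_left", "ms_ssim"):
        by_method = {m: report.loc[report.method == m, metric].to_numpy()
                     for m in methods}
        if len(report) // max(len(methods), 1) < 3:
            log.warning("stats: too few test images for paired tests, skipping")
            break
        table = pairwise_table(by_method, metric=metric)
        table.to_csv(stats_dir / f"pvalues_{metric}.csv")
        tables[metric] = table
    ages = age_group_summary(report, config.age_group_width)
    ages.to_csv(stats_dir / "age_groups.csv")
    tables["age_groups"] = ages
    return tables


def run_pipeline(config: PipelineConfig, force: bool = False,
                 stages: Sequence[str] = STAGES) -> Path:
    """Run the requested stages in order; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, outdir)

    records = pairs = checkpoints = report = None
    try:
        records = stage_simulate(config, outdir, force)
        pairs = stage_prepare(config, outdir, records, force)
        if "train" in stages or "evaluate" in stages or "stats" in stages:
            checkpoints = stage_train(config, outdir, pairs,
                                      force and "train" in stages)
        if "evaluate" in stages or "stats" in stages:
            report = stage_evaluate(config, outdir, pairs, checkpoints, force)
        if "stats" in stages:
            stage_stats(config, outdir, report, force)
    except Exception as exc:
        stage = "simulate" if records is None else \
            "prepare" if pairs is None else \
            "train" if checkpoints is None else \
            "evaluate" if report is None else "stats"
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir
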