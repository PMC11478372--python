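"""End-to-end orchestration: one config, one seeded reproducible run.

``run_pipeline`` wires the stages together — synthesize (or load) records,
optionally EEMD-denoise, detect R peaks, segment, standardize, balance,
split, train, evaluate — and writes every artifact (segment CSV, weight
checkpoint, history, confusion matrix, JSON manifest) into one output
directory. The manifest records seeds, counts, configs and metrics so a
run can be re-created exactly.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .denoise import EEMDConfig, denoise_signal
from .io import (
    CLASS_LABELS,
    ECGRecord,
    map_annotation_symbols,
    read_segments_csv,
    read_wfdb_record,
    write_segments_csv,
)
from .model import ArchitectureConfig, build_model, save_model
from .preprocess import (
    RPeakSet,
    SegmentDataset,
    balance_classes,
    detect_rpeaks,
    segment_beats,
    split_dataset,
    zscore_segment,
)
from .synth import NoiseSpec, add_noise, default_templates, generate_record
from .train_eval import TrainConfig, evaluate_model, train_model


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-serializable.

    ``source`` selects the input route: ``"synthetic"`` generates one
    record per class and runs the full denoise/detect/segment chain;
    ``"csv"`` loads already-segmented beats; ``"wfdb"`` reads annotated
    records and segments them at the expert R labels.
    """

    seed: int = 0
    outdir: str = "run"
    source: str = "synthetic"
    # synthetic-record generation
    beats_per_class: int = 120
    heart_rate: float = 75.0
    noise: dict = field(default_factory=lambda: {
        "white_sd": 0.05, "baseline_amp": 0.1, "powerline_amp": 0.02})
    # loading
    csv_path: str | None = None
    wfdb_paths: list[str] = field(default_factory=list)
    lead: str = "MLII"
    # denoising
    denoise_enabled: bool = True
    eemd_trials: int = 8
    eemd_noise_sd_frac: float = 0.2
    drop_leading_imfs: int = 1
    # detection / segmentation
    use_truth_rpeaks: bool = False
    # balancing / split
    balance_target: int | None = None
    train_frac: float = 0.7
    val_frac_of_train: float = 0.1
    stratified: bool = True
    # model / training
    architecture: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _label_rpeaks(
    detected: RPeakSet, truth_idx: np.ndarray, truth_labels: list[str],
    tol_samples: int,
) -> tuple[RPeakSet, list[str]]:
    """Keep detections matching a truth R peak; attach that peak's label."""
    kept, labels = [], []
    for d in detected.indices:
        j = int(np.argmin(np.abs(truth_idx - d)))
        if abs(int(truth_idx[j]) - int(d)) <= tol_samples:
            kept.append(int(d))
            labels.append(truth_labels[j])
    return RPeakSet(indices=np.array(kept, dtype=np.int64), fs=detected.fs), labels


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc
    return wrap


def _build_dataset(config: PipelineConfig, manifest: dict) -> SegmentDataset:
    segments = []
    drops = {"unmatched_detections": 0}
    if config.source == "csv":
        if not config.csv_path:
            raise ValueError("source 'csv' requires csv_path")
        segments = read_segments_csv(config.csv_path)
    elif config.source in ("synthetic", "wfdb"):
        if config.source == "synthetic":
            noise = NoiseSpec(seed=config.seed, **config.noise)
            inputs = []
            for k, label in enumerate(CLASS_LABELS):
                record, r_idx, labels = generate_record(
                    [label] * config.beats_per_class,
                    heart_rate=config.heart_rate,
                    templates=default_templates(),
                    seed=config.seed + 1000 + k,
                )
                inputs.append((add_noise(record, noise), r_idx, labels))
        else:
            inputs = []
            for base in config.wfdb_paths:
                record, anns = read_wfdb_record(base, lead=config.lead)
                pairs = map_annotation_symbols(anns)
                idx = np.array([p[0] for p in pairs], dtype=np.int64)
                inputs.append((record, idx, [p[1] for p in pairs]))
        for record, truth_idx, truth_labels in inputs:
            if config.denoise_enabled:
                denoised = denoise_signal(
                    record.samples,
                    EEMDConfig(n_trials=config.eemd_trials,
                               noise_sd_frac=config.eemd_noise_sd_frac,
                               seed=config.seed),
                    drop_leading=config.drop_leading_imfs,
                )
                record = ECGRecord(samples=denoised, fs=record.fs,
                                   lead=record.lead, source_id=record.source_id)
            if config.use_truth_rpeaks:
                rpeaks = RPeakSet(indices=truth_idx, fs=record.fs)
                labels = list(truth_labels)
            else:
                detected = detect_rpeaks(record)
                tol = int(round(0.05 * record.fs))
                rpeaks, labels = _label_rpeaks(detected, truth_idx, truth_labels, tol)
                drops["unmatched_detections"] += len(detected) - len(rpeaks)
            segments.extend(segment_beats(record, rpeaks, labels=labels))
        segments = [zscore_segment(s) for s in segments]
    else:
        raise ValueError(f"unknown source {config.source!r}")
    manifest["drops"] = drops
    return SegmentDataset(
        segments=segments,
        provenance={"source": config.source, "seed": config.seed},
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured chain and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": sys.version.split()[0],
        "seed": config.seed,
        "config": asdict(config),
    }

    dataset = _stage("ingest")(_build_dataset, config, manifest)
    manifest["class_counts_raw"] = dataset.class_counts

    if config.balance_target:
        dataset = _stage("balance")(
            balance_classes, dataset, config.balance_target, config.seed)
    manifest["class_counts_balanced"] = dataset.class_counts
    manifest["n_segments"] = len(dataset)

    _stage("export")(write_segments_csv, dataset.segments, outdir / "segments.csv")

    train_set, val_set, test_set = _stage("split")(
        split_dataset, dataset, config.train_frac, config.val_frac_of_train,
        config.seed, config.stratified)
    manifest["split_sizes"] = {
        "train": len(train_set), "val": len(val_set), "test": len(test_set)}

    arch = ArchitectureConfig(**{
        k: v for k, v in config.architecture.items()}) if config.architecture \
        else ArchitectureConfig()
    train_cfg = TrainConfig(seed=config.seed, **config.train) if config.train \
        else TrainConfig(seed=config.seed)
    model = _stage("build")(build_model, arch, config.seed)
    val_arg = val_set if len(val_set) else test_set  # val carve-out may be 0
    model, history = _stage("train")(train_model, model, train_set, val_arg, train_cfg)
    history.as_frame().to_csv(outdir / "history.csv", index=False)
    save_model(model, arch, outdir / "weights.npz")
    manifest["stopped_epoch"] = history.stopped_epoch

    report = _stage("evaluate")(evaluate_model, model, test_set)
    np.savetxt(outdir / "confusion.csv", report.confusion, fmt="%d", delimiter=",",
               header=",".join(report.labels), comments="")
    manifest["metrics"] = {
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "n_classes": len(report.labels),
    }
    manifest_out = dict(manifest)
    manifest_out["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest_out, indent=2))
    (outdir / "report.json").write_text(json.dumps(manifest["metrics"], indent=2))
    return manifest
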