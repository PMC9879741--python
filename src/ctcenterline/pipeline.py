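"""End-to-end experiment orchestration.

``run_experiment`` chains simulate -> preprocess -> train -> predict ->
measure -> evaluate into one reproducible run.  Each stage consumes only the
previous stage's serialized outputs (no hidden state), writes into a fixed
directory layout under the run's output directory, and the run manifest
records the configuration hash and seed so a rerun with the same config
reproduces the reports.

Directory layout::

    out/
      manifest.json            run config + hash + seed + stage log
      cohort/                  per-case volume + localizer + ground truth CSV
      pairs/pairs.npz          preprocessed training tensors + crop records
      model.npz                trained checkpoint
      predictions/             reconstructed volumes (NIfTI)
      reports/                 centerline reports and the evaluation tables
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import Grid3D, Volume3D
from . import dicom_io
from .centerline import CenterlineConfig, measure_centerlines
from .metrics import PositioningResults, evaluate_cohort
from .phantom import (Demographics, DEFAULT_MISCENTER_SD, analytic_centerlines,
                      sample_population, simulate_case)
from .preprocess import (PreprocessConfig, TrainingPair, make_training_pair,
                         split_cohort)
from .reconstructor import (LocalizerToVolumeModel, ModelConfig, TrainConfig,
                            preprocess_config_hash)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_experiment"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending case."""

    def __init__(self, stage: str, message: str, case_id: Optional[str] = None):
        self.stage = stage
        self.case_id = case_id
        suffix = f" (case {case_id})" if case_id else ""
        super().__init__(f"stage '{stage}' failed{suffix}: {message}")


@dataclass
class PhantomBlock:
    n_cases: int = 60
    d_ap_cm: Tuple[float, float] = (24.3, 3.6)
    d_lat_cm: Tuple[float, float] = (30.1, 5.3)
    diameter_correlation: float = 0.7
    miscenter_mean: float = 0.0
    miscenter_sd: float = DEFAULT_MISCENTER_SD
    blanket_prob: float = 0.0
    grid_shape: Tuple[int, int, int] = (96, 96, 32)
    grid_spacing: Tuple[float, float, float] = (4.0, 5.0, 6.0)
    divergent: bool = True
    sdd: float = 600.0
    source_id: str = "C1"


@dataclass
class RunConfig:
    """Validated configuration for one experiment run."""

    seed: int = 0
    out_dir: str = "run_output"
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(localizer_shape=(48, 32),
                                                 volume_shape=(64, 48, 32)))
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(depth=3, base_channels=8,
                                            output_ap_bins=64,
                                            input_shape=(48, 32)))
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=20, learning_rate=3e-3))
    centerline: CenterlineConfig = field(default_factory=CenterlineConfig)
    train_fraction: float = 0.8
    identity_prediction: bool = False
    write_dicom: bool = False

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.phantom.n_cases < 2:
            raise ValueError("need at least 2 cases")
        if self.model.input_shape != self.preprocess.localizer_shape:
            raise ValueError("model input_shape must match the preprocess "
                             "localizer_shape")
        if self.model.output_ap_bins != self.preprocess.volume_shape[0]:
            raise ValueError("model output_ap_bins must match the preprocess "
                             "volume AP dimension")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("d_ap_cm", "d_lat_cm", "grid_shape", "grid_spacing"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomBlock(**ph)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            pp["localizer_shape"] = tuple(pp["localizer_shape"])
            pp["volume_shape"] = tuple(pp["volume_shape"])
            d["preprocess"] = PreprocessConfig(**pp)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "centerline" in d and isinstance(d["centerline"], dict):
            d["centerline"] = CenterlineConfig(**d["centerline"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages


def _grid(config: RunConfig) -> Grid3D:
    return Grid3D.centered(config.phantom.grid_shape,
                           config.phantom.grid_spacing)


def stage_simulate(config: RunConfig, out: Path) -> pd.DataFrame:
    """Generate the cohort; write volumes/localizers and a ground-truth CSV."""
    ph = config.phantom
    grid = _grid(config)
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    specs = sample_population(
        ph.n_cases,
        demographics=Demographics(d_ap_cm=ph.d_ap_cm, d_lat_cm=ph.d_lat_cm,
                                  correlation=ph.diameter_correlation),
        miscenter_sd=ph.miscenter_sd,
        miscenter_mean=ph.miscenter_mean,
        blanket_prob=ph.blanket_prob,
        seed=config.seed,
    )
    rows = []
    for i, spec in enumerate(specs):
        case_id = f"case{i:04d}"
        try:
            case = simulate_case(spec, grid, case_id=case_id,
                                 divergent=ph.divergent, sdd=ph.sdd)
        except ValueError as exc:
            raise StageError("simulate", str(exc), case_id)
        case.volume.source_id = ph.source_id
        case.localizer.source_id = ph.source_id
        case_dir = cohort_dir / case_id
        if config.write_dicom:
            dicom_io.write_axial_series(case.volume, case_dir / "series",
                                        source_id=ph.source_id)
            dicom_io.write_localizer(case.localizer, case_dir / "scout.dcm",
                                     source_id=ph.source_id)
            vol_path = case_dir / "series"
        else:
            vol_path = dicom_io.write_volume_nifti(case.volume,
                                                   case_dir / "volume.nii")
            np.savez(case_dir / "localizer.npz",
                     pixels=case.localizer.pixels,
                     pixel_spacing=case.localizer.pixel_spacing,
                     position=case.localizer.position)
        gt = case.ground_truth
        rows.append({
            "case_id": case_id,
            "path": str(vol_path),
            "source_id": ph.source_id,
            "d_ap_mm": 2 * spec.body_semi_axis_ap,
            "d_lat_mm": 2 * spec.body_semi_axis_lat,
            "table_height_offset_mm": spec.table_height_offset,
            "blanket": spec.blanket_present,
            "gt_body_centerline_mm": gt.body_centerline,
            "gt_lung_centerline_mm": gt.lung_centerline,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(cohort_dir / "ground_truth.csv", index=False)
    return manifest


def _load_case(config: RunConfig, case_dir: Path):
    from .core import Localizer2D

    if config.write_dicom:
        volume = dicom_io.read_axial_series(case_dir / "series")
        localizer = dicom_io.read_localizer(case_dir / "scout.dcm")
    else:
        volume = dicom_io.read_volume_nifti(case_dir / "volume.nii")
        with np.load(case_dir / "localizer.npz") as data:
            localizer = Localizer2D(pixels=data["pixels"],
                                    pixel_spacing=tuple(data["pixel_spacing"]),
                                    position=tuple(data["position"]),
                                    source_id=config.phantom.source_id)
    return volume, localizer


def stage_preprocess(config: RunConfig, out: Path,
                     manifest: pd.DataFrame) -> Tuple[List[TrainingPair], dict]:
    """Build training pairs from the serialized cohort; split train/test."""
    pairs = []
    for case_id in manifest["case_id"]:
        case_dir = out / "cohort" / case_id
        try:
            volume, localizer = _load_case(config, case_dir)
            pair = make_training_pair(localizer, volume, config.preprocess,
                                      case_id=case_id)
        except Exception as exc:
            raise StageError("preprocess", str(exc), case_id)
        pairs.append(pair)
    train, test = split_cohort(pairs, fraction=config.train_fraction,
                               seed=config.seed)
    split = {"train": [p.case_id for p in train],
             "test": [p.case_id for p in test]}
    pairs_dir = out / "pairs"
    pairs_dir.mkdir(exist_ok=True)
    np.savez_compressed(
        pairs_dir / "pairs.npz",
        localizers=np.stack([p.localizer_in for p in pairs]),
        volumes=np.stack([p.volume_out for p in pairs]),
        case_ids=np.array([p.case_id for p in pairs]),
    )
    (pairs_dir / "crop_records.json").write_text(json.dumps(
        {p.case_id: p.crop_record.to_dict() for p in pairs}))
    (pairs_dir / "split.json").write_text(json.dumps(split))
    return pairs, split


def stage_train(config: RunConfig, out: Path,
                pairs: List[TrainingPair], split: dict) -> LocalizerToVolumeModel:
    train_pairs = [p for p in pairs if p.case_id in set(split["train"])]
    model = LocalizerToVolumeModel(config.model, seed=config.seed)
    model.preprocess_hash = preprocess_config_hash(config.preprocess)
    try:
        results = model.fit(train_pairs, config.train)
    except (RuntimeError, ValueError) as exc:
        raise StageError("train", str(exc))
    (out / "loss_history.json").write_text(json.dumps(results.loss_history))
    model.save(out / "model.npz")
    logger.info("train: %d pairs, %d epochs, final loss %s",
                len(train_pairs), len(results.loss_history),
                results.final_loss)
    return model


def stage_predict(config: RunConfig, out: Path, model: LocalizerToVolumeModel,
                  pairs: List[TrainingPair], split: dict) -> dict:
    """Reconstruct volumes for the test cases (or copy ground truth through
    in identity mode, the pipeline's self-check)."""
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    predicted = {}
    for pair in pairs:
        if pair.case_id not in set(split["test"]):
            continue
        try:
            if config.identity_prediction:
                volume, _ = _load_case(config, out / "cohort" / pair.case_id)
            else:
                volume = model.predict_volume(pair.localizer_in,
                                              pair.crop_record)
            dicom_io.write_volume_nifti(volume,
                                        pred_dir / f"{pair.case_id}.nii")
            predicted[pair.case_id] = volume
        except Exception as exc:
            raise StageError("predict", str(exc), pair.case_id)
    return predicted


def stage_measure(config: RunConfig, out: Path, split: dict,
                  predicted: dict) -> List[dict]:
    """Measure centerlines on ground-truth and predicted test volumes."""
    reports = []
    for case_id in split["test"]:
        try:
            gt_volume, _ = _load_case(config, out / "cohort" / case_id)
            rep_gt = measure_centerlines(gt_volume, config.centerline,
                                         source="ground_truth")
            rep_dl = measure_centerlines(predicted[case_id], config.centerline,
                                         source="predicted")
        except Exception as exc:
            raise StageError("measure", str(exc), case_id)
        reports.append({"case_id": case_id, "gt": rep_gt, "dl": rep_dl})
    return reports


def stage_evaluate(config: RunConfig, out: Path, manifest: pd.DataFrame,
                   reports: List[dict]) -> PositioningResults:
    sizes = {}
    for _, row in manifest.iterrows():
        sizes[row["case_id"]] = float(
            np.sqrt(row["d_ap_mm"] * row["d_lat_mm"]))
    try:
        results = evaluate_cohort(
            [(r["gt"], r["dl"]) for r in reports],
            isocenter_y=0.0,
            case_ids=[r["case_id"] for r in reports],
            body_sizes=[sizes[r["case_id"]] for r in reports],
            seed=config.seed,
        )
    except ValueError as exc:
        raise StageError("evaluate", str(exc))
    rep_dir = out / "reports"
    rep_dir.mkdir(exist_ok=True)
    results.summary_table.table.to_csv(rep_dir / "summary.csv")
    results.tests.to_csv(rep_dir / "tests.csv", index=False)
    per_case = pd.DataFrame([
        {"case_id": e.case_id, "bcap": e.bcap, "bcmp": e.bcmp,
         "lcap": e.lcap, "lcmp": e.lcmp, "body_size": e.body_size}
        for e in results.errors
    ])
    per_case.to_csv(rep_dir / "per_case_errors.csv", index=False)
    (rep_dir / "summary.txt").write_text(results.summary())
    return results


def run_experiment(config: RunConfig) -> PositioningResults:
    """Run the whole pipeline; see the module docstring for the layout."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log = []

    def _log(stage, t0):
        stage_log.append({"stage": stage, "seconds": round(time.time() - t0, 2)})
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    t0 = time.time()
    manifest = stage_simulate(config, out)
    _log("simulate", t0)
    t0 = time.time()
    pairs, split = stage_preprocess(config, out, manifest)
    _log("preprocess", t0)
    t0 = time.time()
    if config.identity_prediction:
        model = None
    else:
        model = stage_train(config, out, pairs, split)
    _log("train", t0)
    t0 = time.time()
    predicted = stage_predict(config, out, model, pairs, split)
    _log("predict", t0)
    t0 = time.time()
    reports = stage_measure(config, out, split, predicted)
    _log("measure", t0)
    t0 = time.time()
    results = stage_evaluate(config, out, manifest, reports)
    _log("evaluate", t0)

    (out / "manifest.json").write_text(json.dumps({
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stage_log,
        "n_excluded_truncated": results.n_excluded,
    }, default=str, indent=1))
    return results
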