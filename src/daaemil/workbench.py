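"""Formats, configuration, seeding and end-to-end orchestration.

A run is one YAML/JSON-serializable :class:`RunConfig`; :func:`run_pipeline`
executes generate -> normalize -> stage-1 train -> deep-feature extraction ->
per-modality selection -> fusion -> MLP -> evaluation, writing every
intermediate table plus a manifest with content hashes so a rerun with the
same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .backbone import BackboneConfig, Volume, build_backbone
from .exceptions import ConfigurationError, DomainError, VolumeIOError
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "load_volume", "save_volume", "run_pipeline",
           "set_global_seed"]

logger = logging.getLogger("daaemil")


def set_global_seed(seed: int):
    """Seed the legacy global numpy stream; component streams derive from
    the config seed explicitly, this is a safety net for library code."""
    np.random.seed(int(seed) % (2 ** 32))


def load_volume(path) -> Volume:
    """Read a 3-D NIfTI volume; axis order (height, width, depth)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # noqa: BLE001 - surface the path
        raise VolumeIOError(f"cannot read volume at {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DomainError(f"expected a 3-D volume, got shape {data.shape}")
    return Volume(data)


def save_volume(volume: Volume | np.ndarray, path):
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)),
             str(path))


def _demo_cohort() -> CohortConfig:
    # orchestration default: a cohort small enough that `run` finishes in a
    # few CPU-minutes; CohortConfig() itself defaults to the full-size study
    return CohortConfig(n_patients=80, prevalence=0.4)


@dataclass
class RunConfig:
    out_dir: str = "runs/run"
    seed: int = 0
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=_demo_cohort)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    # stage-1 and predictor training overrides (keys of TrainConfig /
    # MlpTrainConfig); empty dict = desk-scale defaults below
    stage1: dict = field(default_factory=lambda: {
        "lr": 1e-3, "max_epochs": 20, "patience": 10})
    predictor: dict = field(default_factory=lambda: {
        "lr": 1e-2, "max_epochs": 60, "patience": 15})
    test_fraction: float = 0.2
    kfolds: int = 5
    screen_alpha: float = 0.05
    write_volumes: bool = False
    n_attention_reports: int = 3
    volumes_dir: str | None = None
    labels_path: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("cohort"), dict):
            d["cohort"] = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["cohort"].items()})
        if isinstance(d.get("backbone"), dict):
            bd = dict(d["backbone"])
            if "widths" in bd:
                bd["widths"] = tuple(bd["widths"])
            if "pools" in bd:
                bd["pools"] = tuple(tuple(p) for p in bd["pools"])
            d["backbone"] = BackboneConfig(**bd)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def validate(self):
        self.cohort.validate()
        self.backbone.validate()
        if not self.synthetic:
            if self.volumes_dir is None or self.labels_path is None:
                raise ConfigurationError(
                    "non-synthetic runs need volumes_dir and labels_path")
            if not Path(self.volumes_dir).exists():
                raise ConfigurationError(f"missing {self.volumes_dir}")
            if not Path(self.labels_path).exists():
                raise ConfigurationError(f"missing {self.labels_path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_params(arrays, path):
    """Timestamp-free binary checkpoint: concatenated float64 buffers.

    Shapes live in the JSON sidecar, so the bytes are a pure function of
    the parameter values and reruns hash identically.
    """
    with open(path, "wb") as fh:
        for a in arrays:
            fh.write(np.ascontiguousarray(a, dtype=np.float64).tobytes())


def load_params(path, shapes):
    arrays = []
    raw = Path(path).read_bytes()
    offset = 0
    for shape in shapes:
        size = int(np.prod(shape)) * 8
        arrays.append(np.frombuffer(raw[offset:offset + size],
                                    dtype=np.float64).reshape(shape).copy())
        offset += size
    return arrays


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    from .daae import (MilModel, TrainConfig, extract_deep_features,
                       train_stage1)
    from .evaluation import (_tabular_block, compute_metrics,
                             export_attention_report, kfold_plan,
                             stratified_patient_split)
    from .fusion import MlpTrainConfig, fuse, predict, train_mlp

    logging.basicConfig(level=config.log_level)
    config.validate()
    set_global_seed(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        return path

    stage = "generate"
    try:
        if not config.synthetic:
            raise ConfigurationError(
                "external-cohort ingestion requires volumes_dir wiring; "
                "only synthetic runs are orchestrated end to end")
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        volumes, clinical, radiomics, truth = generate_cohort(cohort_cfg)
        clinical.to_csv(out / "clinical.csv")
        radiomics.to_csv(out / "radiomics.csv")
        truth.to_json(out / "ground_truth.json")
        written += [out / "clinical.csv", out / "radiomics.csv",
                    out / "ground_truth.json"]
        if config.write_volumes:
            vdir = out / "volumes"
            vdir.mkdir(exist_ok=True)
            for i, v in enumerate(volumes):
                p = vdir / f"P{i:04d}.nii"
                save_volume(v, p)
                written.append(p)

        stage = "split"
        labels = truth.bag_labels
        plan = stratified_patient_split(labels, config.test_fraction,
                                        seed=config.seed)
        train_mask = np.isin(np.arange(len(labels)), plan.train_ids)
        folds = kfold_plan(plan.train_ids, labels[plan.train_ids],
                           K=config.kfolds, seed=config.seed)
        split_path = out / "split.json"
        split_path.write_text(json.dumps({
            "train_ids": plan.train_ids.tolist(),
            "test_ids": plan.test_ids.tolist(),
            "folds": {str(k): int(v) for k, v in folds.items()},
        }))
        written.append(split_path)

        stage = "stage1-train"
        extractor = build_backbone(config.backbone,
                                   input_shape=volumes.shape[1:])
        model = MilModel(extractor, pooling="daae", seed=config.seed)
        tcfg = TrainConfig(seed=config.seed, **config.stage1)
        model, log = train_stage1(volumes[train_mask], labels[train_mask],
                                  model, tcfg)
        log_path = out / "stage1_log.json"
        log_path.write_text(json.dumps(log))
        written.append(log_path)
        ckpt = out / "stage1_model.bin"
        save_params(model.state_arrays(), ckpt)
        (out / "stage1_model.json").write_text(json.dumps({
            "seed": config.seed, "m_inference": model.m_inference,
            "shapes": [list(a.shape) for a in model.state_arrays()],
            "backbone": asdict(config.backbone)}))
        written += [ckpt, out / "stage1_model.json"]

        stage = "deep-features"
        deep = extract_deep_features(model, volumes,
                                     patient_ids=clinical.patient_ids)
        deep.to_csv(out / "deep_features.csv")
        written.append(out / "deep_features.csv")

        stage = "feature-selection"
        blocks = {
            "clinical": _tabular_block(clinical, labels, train_mask,
                                       screen_alpha=config.screen_alpha,
                                       seed=config.seed),
            "radiomics": _tabular_block(radiomics, labels, train_mask,
                                        seed=config.seed),
            "deep": _tabular_block(deep, labels, train_mask, seed=config.seed),
        }
        for name, tab in blocks.items():
            if tab is not None:
                tab.to_csv(out / f"selected_{name}.csv")
                written.append(out / f"selected_{name}.csv")

        stage = "fusion"
        fused = fuse(blocks["clinical"], blocks["radiomics"], blocks["deep"],
                     allow_missing=True)
        fused_df = pd.DataFrame(fused.values)
        fused_df.insert(0, "patient_id", fused.patient_ids)
        save_df(fused_df, "fused.csv")

        stage = "predictor-train"
        mcfg = MlpTrainConfig(seed=config.seed, **config.predictor)
        params = train_mlp(fused.values[train_mask], labels[train_mask], mcfg)
        scores, classes = predict(params, fused.values)
        pred_df = pd.DataFrame({"patient_id": fused.patient_ids,
                                "probability": scores, "class": classes})
        save_df(pred_df, "predictions.csv")

        stage = "evaluate"
        report = compute_metrics(labels[~train_mask], scores[~train_mask],
                                 ci=True, ci_seed=config.seed)
        fold_rows = []
        fold_of = np.full(len(labels), -1)
        for pid, f in folds.items():
            fold_of[pid] = f
        for f in range(config.kfolds):
            va = fold_of == f
            tr = train_mask & ~va
            cfgf = MlpTrainConfig(seed=config.seed, **config.predictor)
            pf = train_mlp(fused.values[tr], labels[tr], cfgf)
            sf, _ = predict(pf, fused.values[va])
            rep = compute_metrics(labels[va], sf)
            fold_rows.append({"fold": f, **rep.as_dict()})
        eval_payload = {"test": report.as_dict(), "cv_folds": fold_rows}
        eval_path = out / "eval_report.json"
        eval_path.write_text(json.dumps(eval_payload, indent=2))
        written.append(eval_path)
        save_df(pd.DataFrame(fold_rows), "cv_folds.csv")

        stage = "attention-reports"
        pos_test = [int(i) for i in plan.test_ids if labels[i] == 1]
        for pid in pos_test[:config.n_attention_reports]:
            p = out / f"attention_P{pid:04d}.csv"
            export_attention_report(model, volumes[pid], f"P{pid:04d}", path=p)
            written.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict())),
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(written), out)
    return out
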