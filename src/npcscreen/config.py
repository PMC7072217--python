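"""Pipeline configuration and the end-to-end run.

A single YAML file describes a whole experiment: the synthetic dataset (one
slide template plus per-split counts), the patch- and slide-stage training
hyperparameters, and the evaluation protocol.  ``run_pipeline`` executes
simulate -> train-patch -> build-maps -> train-slide -> evaluate and writes
a machine-readable JSON report carrying every metric, per-stage seed,
checkpoint hash and timing, so any artifact can be regenerated from the
config alone.

One global seed is fanned out deterministically to the stages through
``numpy.random.SeedSequence([seed, stage_index])``, so stages can be rerun
in isolation and still see the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotations import TrainingClass  # noqa: F401 (used in evaluate stage)
from .patch_pipeline import PatchClassifier, SlideDataset, TrainingConfig
from .slide_pipeline import (
    SlideClassifier,
    build_probability_map,
    compose_slide_input,
    infer_slide,
    save_probability_map,
)
from .synthetic_wsi import SlideSpec, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_config"]

logger = logging.getLogger("npcscreen")

_STAGES = {"simulate": 0, "train_patch": 1, "build_maps": 2,
           "train_slide": 3, "evaluate": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SyntheticBlock:
    width: int = 1280
    height: int = 1024
    tumor_fraction: float = 0.18
    confuser_density: int = 4
    n_train: int = 8        # per split, NPC + benign in equal halves
    n_val: int = 4
    n_test: int = 6


@dataclass
class StageTraining:
    learning_rate: float = 0.0017
    momentum: float = 0.95
    eval_interval: int = 1000
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    min_lr: float = 1e-6
    max_steps: int = 3000


@dataclass
class EvaluationBlock:
    runs: int = 30
    n_patches: int = 16_000
    threshold: float = 0.5


@dataclass
class PipelineConfig:
    out_dir: str = "npcscreen_run"
    seed: int = 0
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    patch: StageTraining = field(default_factory=StageTraining)
    slide: StageTraining = field(default_factory=lambda: StageTraining(
        eval_interval=100, max_steps=600))
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        return cls(
            out_dir=doc.get("out_dir", "npcscreen_run"),
            seed=int(doc.get("seed", 0)),
            synthetic=SyntheticBlock(**doc.get("synthetic", {})),
            patch=StageTraining(**doc.get("patch", {})),
            slide=StageTraining(**{"eval_interval": 100, "max_steps": 600,
                                   **doc.get("slide", {})}),
            evaluation=EvaluationBlock(**doc.get("evaluation", {})),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _dataset_from_manifest(manifest, split):
    return SlideDataset.from_manifest(manifest, split=split)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-to-evaluation pipeline; returns the report.

    Any stage failure aborts with the stage name in the exception; partial
    outputs written so far are left in place.
    """
    from .evaluation import _balanced_test_patches, auc, sens_spec

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(),
                    "config_hash": config.content_hash(),
                    "seed": config.seed,
                    "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
                    "stages": {}, "timings": {}}

    def run_stage(name, fn):
        t0 = time.time()
        logger.info("stage %s: start", name)
        try:
            report["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["timings"][name] = round(time.time() - t0, 2)
        logger.info("stage %s: done in %.1fs", name, report["timings"][name])

    # -- simulate -----------------------------------------------------------
    syn = config.synthetic
    data_dir = out / "slides"

    def _simulate():
        template = SlideSpec(width=syn.width, height=syn.height,
                             tumor_fraction=syn.tumor_fraction,
                             confuser_density=syn.confuser_density,
                             seed=stage_seed(config.seed, "simulate"), label="NPC")
        n_total = syn.n_train + syn.n_val + syn.n_test
        fr = {"train": syn.n_train / n_total, "val": syn.n_val / n_total,
              "test": syn.n_test / n_total}
        df = generate_dataset(n_total // 2, n_total - n_total // 2,
                              template, data_dir, split_fractions=fr)
        return {"n_slides": len(df), "manifest": str(data_dir / "manifest.csv"),
                "splits": df["split"].value_counts().to_dict()}

    run_stage("simulate", _simulate)
    manifest = data_dir / "manifest.csv"
    train_ds = _dataset_from_manifest(manifest, "train")
    val_ds = _dataset_from_manifest(manifest, "val")
    test_ds = _dataset_from_manifest(manifest, "test")

    # -- patch stage ---------------------------------------------------------
    patch_ckpt = out / "patch_model.npz"

    def _train_patch():
        est = PatchClassifier(
            learning_rate=config.patch.learning_rate, momentum=config.patch.momentum,
            eval_interval=config.patch.eval_interval,
            plateau_factor=config.patch.plateau_factor,
            plateau_patience=config.patch.plateau_patience,
            min_lr=config.patch.min_lr, max_steps=config.patch.max_steps,
            seed=stage_seed(config.seed, "train_patch"))
        est.fit(train_ds, validation=val_ds)
        est.save(patch_ckpt)
        est.curves_.to_csv(out / "patch_curves.csv", index=False)
        return {"checkpoint": str(patch_ckpt), "checkpoint_hash": _file_hash(patch_ckpt),
                "final_val_loss": float(est.curves_["val_loss"].iloc[-1]),
                "final_val_auc": float(est.curves_["val_auc"].iloc[-1])}

    run_stage("train_patch", _train_patch)
    patch_model = PatchClassifier.load(patch_ckpt)

    # -- probability maps ----------------------------------------------------
    maps_dir = out / "maps"
    inputs: dict[str, list] = {}

    def _build_maps():
        maps_dir.mkdir(exist_ok=True)
        for split, ds in (("train", train_ds), ("val", val_ds), ("test", test_ds)):
            items = []
            for rec in ds:
                pmap = build_probability_map(patch_model, rec.image,
                                             slide_id=rec.slide_id,
                                             checkpoint_id=_file_hash(patch_ckpt))
                save_probability_map(pmap, maps_dir / f"{rec.slide_id}.tif")
                items.append((compose_slide_input(pmap, rec.image, label=rec.label),
                              1 if rec.label == "NPC" else 0))
            inputs[split] = items
        return {"n_maps": sum(len(v) for v in inputs.values()), "dir": str(maps_dir)}

    run_stage("build_maps", _build_maps)

    # -- slide stage ---------------------------------------------------------
    slide_ckpt = out / "slide_model.npz"

    def _train_slide():
        xs = [si for si, _ in inputs["train"]]
        ys = np.array([lab for _, lab in inputs["train"]])
        xv = [si for si, _ in inputs["val"]]
        yv = np.array([lab for _, lab in inputs["val"]])
        sc = SlideClassifier(
            learning_rate=config.slide.learning_rate, momentum=config.slide.momentum,
            eval_interval=config.slide.eval_interval,
            plateau_factor=config.slide.plateau_factor,
            plateau_patience=config.slide.plateau_patience,
            min_lr=config.slide.min_lr, max_steps=config.slide.max_steps,
            seed=stage_seed(config.seed, "train_slide"))
        sc.fit(xs, ys, validation=(xv, yv))
        sc.save(slide_ckpt)
        sc.curves_.to_csv(out / "slide_curves.csv", index=False)
        return {"checkpoint": str(slide_ckpt),
                "checkpoint_hash": _file_hash(slide_ckpt),
                "final_val_loss": float(sc.curves_["val_loss"].iloc[-1])}

    run_stage("train_slide", _train_slide)

    # -- evaluation ----------------------------------------------------------
    def _evaluate():
        rng = np.random.default_rng(stage_seed(config.seed, "evaluate"))
        n = min(config.evaluation.n_patches, 2000)  # patch-level snapshot
        x, y = _balanced_test_patches(test_ds, n, rng)
        p = patch_model.predict_proba(x)[:, TrainingClass.NPC.value]
        patch_auc = auc(p, y)
        slide_model = SlideClassifier.load(slide_ckpt)
        scores = np.array([infer_slide(slide_model, si) for si, _ in inputs["test"]])
        labels = np.array([lab for _, lab in inputs["test"]])
        slide_auc = auc(scores, labels)
        sens, spec = sens_spec(scores, labels, config.evaluation.threshold)
        return {"patch_auc": float(patch_auc), "slide_auc": float(slide_auc),
                "slide_sensitivity": float(sens), "slide_specificity": float(spec),
                "n_patch_eval": int(n)}

    run_stage("evaluate", _evaluate)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    logger.info("report written to %s", report_path)
    return report
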