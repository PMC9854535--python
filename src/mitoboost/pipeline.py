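"""End-to-end orchestration: simulate -> segment -> features -> tune -> fit -> evaluate.

The default desk-scale segmentation backend is intensity thresholding of the
inverted image plus connected-component patch extraction (the pyramid-pooling
operators are forward-only and carry no trained weights).  All randomness
flows from the config seed; every derived seed is written to the run log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import ahba, features, gboost, metrics, ppm, synthetic, tuner

logger = logging.getLogger("mitoboost")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Strict):
    source: str = Field("images", pattern="^(images|table)$")
    n_per_class: int = 75
    patch_size: int = 64
    noise_sd: float = 0.04
    # feature-table source
    dim: int = 5
    shift: float = 2.0


class SegmentationConfig(_Strict):
    backend: str = Field("threshold", pattern="^(threshold|ppm-fixed)$")
    threshold: float = 0.5
    min_area: int = 20
    patch_size: int = 48


class SplitConfig(_Strict):
    train_fraction: float = 0.7
    train_counts: dict[int, int] | None = None


class TunerConfig(_Strict):
    enabled: bool = True
    birds: int = 8
    iterations: int = 20
    folds: int = 5


class BoostDefaults(_Strict):
    num_rounds: int = 50
    max_depth: int = 3
    shrinkage: float = 0.1
    lam: float = 1.0
    gamma: float = 0.0
    min_child_hessian: float = 0.0


class NetworkStandInConfig(_Strict):
    """Settings for the toy network stand-ins trained with Adamax."""

    learning_rate: float = 0.01
    dropout: float = 0.5
    batch_size: int = 5
    epochs: int = 50


class PipelineConfig(_Strict):
    seed: int = 0
    data: DataConfig = DataConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    split: SplitConfig = SplitConfig()
    tuner: TunerConfig = TunerConfig()
    boost: BoostDefaults = BoostDefaults()
    network: NetworkStandInConfig = NetworkStandInConfig()


def load_config(path) -> PipelineConfig:
    """Schema-validated config with defaults filled; unknown keys rejected."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        offending = sorted({".".join(str(p) for p in e["loc"]) for e in exc.errors()})
        raise ValueError(f"invalid pipeline config; offending keys: {offending}") from exc


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2) + "\n")


def segment_patches(images, labels, seg: SegmentationConfig):
    """Threshold-backend candidate extraction; one patch per image.

    The largest surviving component wins; an image with no candidate falls
    back to its center crop so no labeled sample is silently dropped.
    """
    patches, kept_labels, n_fallback = [], [], 0
    for img, lab in zip(images, labels):
        prob = synthetic.probability_map(img)
        cands = ppm.extract_candidate_patches(
            prob, threshold=seg.threshold, min_area=seg.min_area,
            patch_size=seg.patch_size)
        if cands:
            best = max(cands, key=lambda c: c.area)
            patches.append(ppm.crop_patch(img, best))
        else:
            n_fallback += 1
            h, w = img.shape
            s = min(seg.patch_size, h, w)
            y0, x0 = (h - s) // 2, (w - s) // 2
            patches.append(img[y0:y0 + s, x0:x0 + s])
        kept_labels.append(lab)
    if n_fallback:
        logger.info("segmentation found no candidate in %d images; used center crops",
                    n_fallback)
    return patches, np.asarray(kept_labels)


def _feature_table(config: PipelineConfig, seed: int) -> pd.DataFrame:
    if config.data.source == "table":
        return synthetic.generate_feature_table(
            config.data.n_per_class, config.data.dim, config.data.shift, seed)
    spec = synthetic.PatchSpec(size=config.data.patch_size, noise_sd=config.data.noise_sd)
    images, labels, _ = synthetic.generate_patch_dataset(
        config.data.n_per_class, spec, seed)
    patches, labels = segment_patches(images, labels, config.segmentation)
    return features.descriptor_table(patches, labels)


def run_end_to_end(config: PipelineConfig, outdir) -> dict:
    """Full pipeline run; writes all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    seeds = {"data": seed, "split": seed + 1, "tune": seed + 2}
    log_lines = [f"seed.{k} = {v}" for k, v in seeds.items()]

    save_config(config, outdir / "config.json")

    table = _feature_table(config, seeds["data"])
    X, y = features.split_table(table)

    split = synthetic.SplitSpec(train_fraction=config.split.train_fraction,
                                train_counts=config.split.train_counts,
                                seed=seeds["split"])
    train_idx, test_idx = synthetic.split_dataset(X, y, split)
    log_lines.append(f"split: {train_idx.size} train / {test_idx.size} test")

    bd = config.boost
    boost_config = gboost.BoostConfig(
        num_rounds=bd.num_rounds, max_depth=bd.max_depth, shrinkage=bd.shrinkage,
        lam=bd.lam, gamma=bd.gamma, min_child_hessian=bd.min_child_hessian)
    best_params: dict = {}
    if config.tuner.enabled:
        cfg = ahba.AHBAConfig(n=config.tuner.birds, max_iters=config.tuner.iterations,
                              seed=seeds["tune"])
        result = tuner.tune(X[train_idx], y[train_idx], ahba_config=cfg,
                            k=config.tuner.folds, seed=seeds["tune"])
        best_params = result.best_params
        boost_config = tuner._config_from_params(best_params)
        pd.DataFrame({"iteration": np.arange(result.history.size),
                      "best_fitness": result.history}).to_csv(
            outdir / "trace.csv", index=False)
        log_lines.append(f"tuning: {result.n_evals} unique CV evaluations, "
                         f"best CV error {result.best_cv_error:.4f}")
    (outdir / "best_params.json").write_text(json.dumps(best_params, indent=2) + "\n")

    model = gboost.fit(X[train_idx], y[train_idx], boost_config)
    (outdir / "model.json").write_text(model.to_json() + "\n")

    report: dict = {"seeds": seeds, "best_params": best_params}
    frames = []
    confusion_rows = []
    for phase, idx in (("train", train_idx), ("test", test_idx)):
        cm = metrics.confusion_from_labels(y[idx], model.predict(X[idx]))
        tab = metrics.metrics_table(cm)
        tab.insert(0, "Phase", phase)
        frames.append(tab.reset_index())
        confusion_rows.append({"phase": phase, "tp": cm.tp, "fn": cm.fn,
                               "fp": cm.fp, "tn": cm.tn})
        report[phase] = {
            "confusion": confusion_rows[-1],
            "balanced_accuracy": metrics.round2(
                metrics.macro_average(metrics.per_class_metrics(cm, True),
                                      metrics.per_class_metrics(cm, False)).accuracy_bal),
        }
    pd.concat(frames, ignore_index=True).to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame(confusion_rows).to_csv(outdir / "confusion.csv", index=False)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
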