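"""End-to-end pipeline: generate -> prep -> train -> predict -> postprocess
-> evaluate, with a run manifest for reproducibility.

The demo configuration is a desk-scale analogue of the full study: smaller
synthetic cores (192 x 640 px, rings ~150 px) with vessel density matched
to ~120 vessels per 680-px ring, 64 x 64 patches and a small transformer
(K = 32, 4 layers) that trains on one CPU in minutes.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import io as rio
from .evaluate import evaluate_delineations, px_to_um
from .infer import InferenceConfig, predict_image
from .preprocess import AugmentConfig, crop_training_patches
from .skeleton import PruneConfig, mask_to_boundaries
from .synthetic import SynthConfig, generate_sample, rasterize_boundaries, write_sample
from .train import TrainConfig, train_model
from .unetr import UNETRConfig, save_checkpoint


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus the global seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    augment: AugmentConfig | None = None
    net: UNETRConfig = field(default_factory=UNETRConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    infer: InferenceConfig = field(default_factory=InferenceConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    n_train_images: int = 4
    n_test_images: int = 3
    patch_stride: int = 48
    stroke_px: int = 3
    min_path_len_px: int = 50
    match_distance_px: float = 15.0
    seed: int = 0


def demo_config(seed: int = 0) -> PipelineConfig:
    """The scaled-down synthetic study configuration (CPU-friendly)."""
    synth = SynthConfig(
        height_px=640,
        width_px=192,
        n_boundaries=3,
        mean_ring_width_px=150.0,
        ring_width_cv=0.15,
        boundary_waviness_px=4.0,
        fiber_band_halfwidth_px=3,
        vessels_per_ring_mean=12.0,
        vessel_radius_range_px=(3.0, 8.0),
        noise_sd=6.0,
        seed=seed,
    )
    return PipelineConfig(
        synth=synth,
        net=UNETRConfig.tiny(image_size=64),
        train=TrainConfig(epochs=40, batch_size=8, learning_rate=1e-3, seed=seed),
        infer=InferenceConfig(patch_size=64, overlap_fraction=0.5),
        prune=PruneConfig(min_branch_area_px=100.0),
        patch_stride=48,
        min_path_len_px=50,
        seed=seed,
    )


def _sample_with_seed(base: SynthConfig, seed: int, sample_id: str):
    cfg = SynthConfig(**{**asdict(base), "seed": seed})
    cfg.vessel_radius_range_px = tuple(base.vessel_radius_range_px)
    sample = generate_sample(cfg)
    sample.image.sample_id = sample_id
    return sample, cfg


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage, writing artifacts under ``out_dir``.

    Returns the evaluation metrics dictionary (also written to
    ``report/metrics.json``). Deterministic for a fixed ``cfg.seed``.
    """
    out = Path(out_dir)
    timings: dict[str, float] = {}
    metrics: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        return name

    # -- generate ----------------------------------------------------------
    stage("generate")
    data_dir = out / "data"
    train_samples, test_samples = [], []
    for i in range(cfg.n_train_images):
        s, sc = _sample_with_seed(cfg.synth, cfg.seed + i, f"train{i}")
        write_sample(s, sc, data_dir)
        train_samples.append(s)
    for i in range(cfg.n_test_images):
        s, sc = _sample_with_seed(cfg.synth, cfg.seed + 1000 + i, f"test{i}")
        write_sample(s, sc, data_dir)
        test_samples.append(s)
    timings["generate"] = time.perf_counter() - timings["generate"]

    # -- prep --------------------------------------------------------------
    stage("prep")
    patches = []
    index_rows = []
    for s in train_samples:
        mask = rasterize_boundaries(s.boundaries, s.image.shape, cfg.stroke_px)
        pairs = crop_training_patches(
            s.image, mask, cfg.net.image_size, cfg.patch_stride
        )
        for p in pairs:
            index_rows.append(
                {
                    "patch_id": len(patches),
                    "sample_id": p.sample_id,
                    "origin_row": p.origin[0],
                    "origin_col": p.origin[1],
                    "n_fg_pixels": int(p.mask.sum()),
                }
            )
            patches.append(p)
    prep_dir = out / "patches"
    prep_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(index_rows).to_csv(prep_dir / "index.csv", index=False)
    timings["prep"] = time.perf_counter() - timings["prep"]

    # -- train -------------------------------------------------------------
    stage("train")
    log_rows = []
    net, history = train_model(
        patches,
        cfg.train,
        cfg.net,
        augment=cfg.augment,
        log=lambda e, l: log_rows.append({"epoch": e, "mean_loss": l}),
    )
    ckpt_dir = out / "ckpt"
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(net, ckpt_dir / "model.npz")
    pd.DataFrame(log_rows).to_csv(ckpt_dir / "training_log.csv", index=False)
    timings["train"] = time.perf_counter() - timings["train"]

    # -- predict / postprocess / evaluate ----------------------------------
    stage("predict")
    pred_dir = out / "pred"
    pred_dir.mkdir(parents=True, exist_ok=True)
    report_rows = []
    n_true = n_recovered = 0
    mismatches, distances = [], []
    n_manual_only = n_predicted_only = 0
    for s in test_samples:
        sid = s.image.sample_id
        prob, mask = predict_image(net, s.image, cfg.infer)
        tifffile.imwrite(pred_dir / f"{sid}_prob.tif", prob.astype(np.float32))
        tifffile.imwrite(pred_dir / f"{sid}_mask.tif", (mask * 255).astype(np.uint8))
        predicted = mask_to_boundaries(mask, cfg.prune, cfg.min_path_len_px)
        rio.write_boundaries(predicted, pred_dir / f"{sid}_boundaries.csv")
        matches = evaluate_delineations(s.boundaries, predicted, s.vessels)
        n_true += len(s.boundaries)
        for m in matches:
            if m.matched:
                distances.append(m.center_distance_px)
                mismatches.append(m.vessel_mismatch)
                if m.center_distance_px <= cfg.match_distance_px:
                    n_recovered += 1
                report_rows.append(
                    {
                        "sample_id": sid,
                        "center_distance_px": m.center_distance_px,
                        "center_distance_um": px_to_um(
                            m.center_distance_px, s.image.resolution_um_per_px
                        ),
                        "vessel_mismatch": m.vessel_mismatch,
                    }
                )
            elif m.manual_only:
                n_manual_only += 1
            else:
                n_predicted_only += 1
    timings["predict"] = time.perf_counter() - timings["predict"]

    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report_rows).to_csv(report_dir / "per_ring.csv", index=False)
    metrics = {
        "n_true_boundaries": n_true,
        "n_matched": len(distances),
        "boundary_recovery_pct": 100.0 * n_recovered / n_true if n_true else 0.0,
        "mean_center_distance_px": float(np.mean(distances)) if distances else float("nan"),
        "mean_vessel_mismatch": float(np.mean(mismatches)) if mismatches else float("nan"),
        "n_manual_only": n_manual_only,
        "n_predicted_only": n_predicted_only,
        "final_train_loss": history[-1],
    }
    (report_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["synth"]["vessel_radius_range_px"] = list(cfg.synth.vessel_radius_range_px)
    return d
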