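"""End-to-end orchestration: scales -> filter bank -> fusion MLP -> mask -> scores.

The full flow mirrors the four-step multiscale detection method: choose a
set of Gaussian scales, correlate the image with the oriented template bank
at every scale, arrange the per-pixel responses as a feature matrix with
ground-truth labels, and train/apply the fusion network.  Segmentation then
binarizes the detection response (Otsu by default) and evaluation reports
ROC area and accuracy.

Everything is driven by a :class:`PipelineConfig`; every run writes its
resolved configuration and the package version next to its outputs, and all
randomness flows from the single configured seed, so identical inputs and
seeds reproduce reports byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__, imgio
from .ann import (
    NetworkArchitecture,
    NetworkModel,
    TrainingConfig,
    predict_image,
    train,
)
from .gmf import ResponseStack, multiscale_response
from .metrics import accuracy, auc, confusion, roc
from .phantom import PhantomConfig, generate_dataset
from .presets import get_preset
from .thresholding import METHODS, LocalParams, segment

__all__ = [
    "PipelineConfig",
    "compute_stack",
    "run_detect",
    "run_segment",
    "run_experiment",
    "seed_stability",
    "pooled_az",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, serializable description of a pipeline run."""

    preset: str = "mgmf"
    sigmas: tuple[float, ...] | None = None  # override the preset's scale list
    L: int | None = None
    T: int | None = None
    kappa: int | None = None
    hidden_sizes: tuple[int, int] = (3, 8)
    use_ann: bool = True
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold_method: str = "otsu"
    threshold_params: LocalParams = field(default_factory=LocalParams)
    n_thresholds: int = 256
    n_repeats: int = 3  # seeded retrainings for the stability table
    seed: int = 0

    def resolved_bank(self) -> tuple[tuple[float, ...], int, int, int]:
        p = get_preset(self.preset)
        sigmas = tuple(self.sigmas) if self.sigmas is not None else p.sigmas
        return (
            sigmas,
            self.L if self.L is not None else p.L,
            self.T if self.T is not None else p.T,
            self.kappa if self.kappa is not None else p.kappa,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigmas"] = list(self.sigmas) if self.sigmas is not None else None
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        gmf = raw.pop("gmf", {})
        for key in ("sigma", "sigmas", "L", "T", "kappa"):
            if key in gmf:
                raw[key if key != "sigma" else "sigmas"] = (
                    [gmf[key]] if key == "sigma" else gmf[key]
                )
        thr = raw.pop("threshold", {})
        if "method" in thr:
            raw["threshold_method"] = thr["method"]
        lp = {k: thr[k] for k in ("window", "k", "R", "bias") if k in thr}
        if lp:
            raw["threshold_params"] = LocalParams(**lp)
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = TrainingConfig(**raw["training"])
        if "sigmas" in raw and raw["sigmas"] is not None:
            raw["sigmas"] = tuple(raw["sigmas"])
        if "hidden_sizes" in raw:
            raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        if "threshold_params" in raw and isinstance(raw["threshold_params"], dict):
            raw["threshold_params"] = LocalParams(**raw["threshold_params"])
        return cls(**raw)


def _write_run_metadata(out_dir: Path, cfg: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "config": cfg.to_dict()}
    (out_dir / "resolved_config.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def compute_stack(image: np.ndarray, cfg: PipelineConfig) -> ResponseStack:
    sigmas, L, T, kappa = cfg.resolved_bank()
    return multiscale_response(image, sigmas, L=L, T=T, kappa=kappa)


def run_detect(
    image_paths,
    out_dir,
    cfg: PipelineConfig,
    model: NetworkModel | None = None,
) -> list[Path]:
    """Detection responses for a set of images, written as PNG + float sidecar.

    With a fusion model, the multiscale stack is fused per pixel; without one
    (``cfg.use_ann`` false, single-scale preset) the raw max-over-orientations
    response of the first scale is emitted — the single-scale baseline path.
    """
    out_dir = Path(out_dir)
    _write_run_metadata(out_dir, cfg)
    written = []
    for path in map(Path, image_paths):
        image = imgio.read_image(path)
        stack = compute_stack(image, cfg)
        if cfg.use_ann:
            if model is None:
                raise ValueError("a trained fusion model is required when use_ann is set")
            if model.architecture.n_inputs != stack.n_scales:
                raise ValueError(
                    f"model expects {model.architecture.n_inputs} scales, "
                    f"config resolves to {stack.n_scales}"
                )
            response = predict_image(model, stack)
        else:
            response = stack.responses[0]
        stem = out_dir / path.stem
        imgio.write_response(stem, response)
        written.append(stem.with_suffix(".npy"))
    return written


def run_segment(response_paths, out_dir, cfg: PipelineConfig) -> list[Path]:
    """Binarize detection responses with the configured thresholding method."""
    out_dir = Path(out_dir)
    _write_run_metadata(out_dir, cfg)
    written = []
    for path in map(Path, response_paths):
        response = imgio.read_response(path)
        mask = segment(response, cfg.threshold_method, cfg.threshold_params)
        target = out_dir / (Path(path).stem + "_mask.png")
        imgio.write_mask(target, mask)
        written.append(target)
    return written


def pooled_az(responses, masks, n_thresholds: int = 256) -> float:
    """A_z over the pooled pixels of several (response, mask) pairs."""
    scores = np.concatenate([np.asarray(r).ravel() for r in responses])
    labels = np.concatenate([np.asarray(m).astype(bool).ravel() for m in masks])
    return auc(roc(scores, labels, n_thresholds))


def _load_dataset(dataset_dir: Path):
    image_dir, mask_dir = dataset_dir / "images", dataset_dir / "masks"
    names = sorted(p.name for p in image_dir.glob("*.png"))
    if not names:
        raise FileNotFoundError(f"no PNG images under {image_dir}")
    images, masks = [], []
    for name in names:
        mask_path = mask_dir / name
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {name}")
        images.append(imgio.read_image(image_dir / name))
        masks.append(imgio.read_mask(mask_path))
    return names, images, masks


def seed_stability(
    stacks_train,
    masks_train,
    stacks_eval,
    masks_eval,
    arch: NetworkArchitecture,
    base_cfg: TrainingConfig,
    n_repeats: int,
) -> dict:
    """Retrain with ``n_repeats`` derived seeds; summary stats of pooled eval A_z."""
    az = []
    for i in range(n_repeats):
        seed = int(np.random.SeedSequence([base_cfg.seed, 0x57AB, i]).generate_state(1)[0] % (2**31))
        model, _ = train(stacks_train, masks_train, arch, replace(base_cfg, seed=seed))
        responses = [predict_image(model, s) for s in stacks_eval]
        az.append(pooled_az(responses, masks_eval))
    az = np.array(az)
    return {
        "runs": n_repeats,
        "max": float(az.max()),
        "min": float(az.min()),
        "mean": float(az.mean()),
        "std": float(az.std()),
        "median": float(np.median(az)),
        "values": [float(v) for v in az],
    }


def run_experiment(dataset_dir, out_dir, cfg: PipelineConfig) -> dict:
    """Train-test experiment on a phantom (or real) dataset directory.

    The images are split 50/50 by sorted-filename parity (even ranks train,
    odd ranks test).  The fusion network is trained on the training half;
    the report carries pooled train/test A_z, per-image A_z, the per-scale
    single-scale baselines, a per-threshold-method accuracy table over the
    test set, and the repeated-seed stability table.  Written as JSON (+ CSV
    for the tables); reruns with the same seed are byte-identical.
    """
    dataset_dir, out_dir = Path(dataset_dir), Path(out_dir)
    _write_run_metadata(out_dir, cfg)
    names, images, masks = _load_dataset(dataset_dir)
    idx = np.arange(len(names))
    train_idx, test_idx = idx[idx % 2 == 0], idx[idx % 2 == 1]
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("dataset too small to split")

    stacks = [compute_stack(im, cfg) for im in images]
    arch = NetworkArchitecture(n_inputs=stacks[0].n_scales, hidden_sizes=cfg.hidden_sizes)
    tr_cfg = replace(cfg.training, seed=cfg.seed)
    stacks_train = [stacks[i] for i in train_idx]
    masks_train = [masks[i] for i in train_idx]
    model, history = train(stacks_train, masks_train, arch, tr_cfg)

    responses = [predict_image(model, s) for s in stacks]
    az_train = pooled_az([responses[i] for i in train_idx], masks_train, cfg.n_thresholds)
    masks_test = [masks[i] for i in test_idx]
    az_test = pooled_az([responses[i] for i in test_idx], masks_test, cfg.n_thresholds)
    per_image_az = {
        names[i]: auc(roc(responses[i], masks[i], cfg.n_thresholds)) for i in idx
    }

    sigmas = stacks[0].sigmas
    single_scale_az = {
        f"{s:g}": pooled_az(
            [stacks[i].responses[j] for i in test_idx], masks_test, cfg.n_thresholds
        )
        for j, s in enumerate(sigmas)
    }

    threshold_table = {}
    for method in METHODS:
        accs = [
            accuracy(confusion(segment(responses[i], method, cfg.threshold_params), masks[i]))
            for i in test_idx
        ]
        threshold_table[method] = float(np.mean(accs))

    stability = seed_stability(
        stacks_train, masks_train, stacks_train, masks_train, arch, tr_cfg, cfg.n_repeats
    ) if cfg.n_repeats > 0 else None

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "train_az": az_train,
        "test_az": az_test,
        "per_image_az": per_image_az,
        "single_scale_test_az": single_scale_az,
        "best_single_scale_test_az": max(single_scale_az.values()),
        "threshold_accuracy": threshold_table,
        "default_threshold_method": cfg.threshold_method,
        "stability": stability,
        "final_training_loss": history.loss[-1] if history.loss else None,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    with open(out_dir / "threshold_accuracy.csv", "w") as fh:
        fh.write("method,accuracy\n")
        for method, acc in sorted(threshold_table.items(), key=lambda kv: -kv[1]):
            fh.write(f"{method},{acc!r}\n")
    return report
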