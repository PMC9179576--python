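"""Two-phase trainer: rotation-pretext pretraining, weight transfer, and grading development.

Phase 1 (pretext) trains backbone + linear head to predict the number of
clockwise quarter-turns applied to an image (4 classes), with plain
cross-entropy and SGD. Phase 2 (development) transfers the backbone weights,
attaches a freshly initialized nonlinear projection head with two outputs,
and trains on observed grade labels with the combined noise/imbalance-aware
objective. The projection learns at the base rate; the pretrained backbone at
``backbone_lr_ratio`` times that. The schedule is a linear warm-up to the
base rate over ``warmup_epochs`` followed by cosine decay to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .cohort import Cohort
from .losses import LossConfig, total_weighted_grad_logits, total_weighted_loss, BatchPrediction
from .nnet import BACKBONES, Model, SGD, Sequential, linear_head, projection_head, softmax
from .preprocess import RotationSample, _to_3ch, augment

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "lr_at",
    "build_model",
    "pretrain",
    "transfer_weights",
    "develop",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    backbone: str = "small_cnn"
    head: str = "nonlinear_projection"  # or "linear"
    n_outputs: int = 2
    init_seed: int = 0
    backbone_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_outputs not in (2, 4):
            raise ValueError("n_outputs must be 2 (grading) or 4 (pretext)")
        if self.head not in ("linear", "nonlinear_projection"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; registered: {sorted(BACKBONES)}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters. Defaults follow the full-scale recipe
    (base LR 0.1 after a 5-epoch warm-up, cosine decay, backbone at 0.1x the
    projection rate, weight decay 1e-4, SGD); epoch counts are set per run
    (60 pretext / 100 develop at full scale, 20 / 25 in the desk profile)."""

    epochs: int = 100
    warmup_epochs: int = 5
    base_lr: float = 0.1
    backbone_lr_ratio: float = 0.1
    weight_decay: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ValueError("need 0 <= warmup_epochs < epochs")
        if self.base_lr <= 0 or self.backbone_lr_ratio <= 0:
            raise ValueError("learning rates must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class TrainedModel:
    model: Model
    spec: ModelSpec
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    pretext_accuracy: Optional[float] = None


def lr_at(epoch: float, config: TrainConfig, part: str = "projection") -> float:
    """Learning rate at a (possibly fractional) epoch for one parameter group.

    Linear ramp from 0 to ``base_lr`` across the warm-up epochs (evaluated at
    epoch + 1, so the first epoch already trains), then cosine decay
    ``base_lr * 0.5 * (1 + cos(pi t))`` with t running 0 -> 1 over the
    remaining epochs. The backbone group is scaled by ``backbone_lr_ratio``.
    """
    if part not in ("projection", "backbone"):
        raise ValueError(f"part must be 'projection' or 'backbone', got {part!r}")
    if epoch < 0 or epoch >= config.epochs:
        raise ValueError(f"epoch must be in [0, {config.epochs}), got {epoch}")
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        lr = config.base_lr * (epoch + 1) / config.warmup_epochs
        lr = min(lr, config.base_lr)
    else:
        t = (epoch - config.warmup_epochs) / (config.epochs - config.warmup_epochs)
        lr = config.base_lr * 0.5 * (1.0 + np.cos(np.pi * t))
    if part == "backbone":
        lr *= config.backbone_lr_ratio
    return float(lr)


def build_model(spec: ModelSpec) -> Model:
    rng = np.random.default_rng(spec.init_seed)
    backbone = BACKBONES[spec.backbone](rng, **spec.backbone_kwargs)
    maker = linear_head if spec.head == "linear" else projection_head
    head = maker(backbone.feature_dim, spec.n_outputs, rng)
    return Model(backbone, head)


def _epoch_pass(
    model: Model,
    opt: SGD,
    x: np.ndarray,
    y: np.ndarray,
    grad_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    loss_fn: Callable[[np.ndarray, np.ndarray], float],
    lrs: list[float],
    batch_size: int,
    rng: np.random.Generator,
    augment_fn: Optional[Callable] = None,
) -> float:
    order = rng.permutation(len(x))
    losses, weights = [], []
    for i in range(0, len(order), batch_size):
        idx = order[i : i + batch_size]
        xb = x[idx]
        if augment_fn is not None:
            xb = np.stack([augment_fn(im, rng) for im in xb])
        yb = y[idx]
        probs = softmax(model.forward(xb, train=True))
        losses.append(loss_fn(probs, yb))
        weights.append(len(idx))
        model.zero_grad()
        model.backward(grad_fn(probs, yb).astype(np.float32))
        opt.step(lrs)
    return float(np.average(losses, weights=weights))


def pretrain(spec: ModelSpec, rotation_data: list[RotationSample], config: TrainConfig) -> TrainedModel:
    """Train a 4-way rotation classifier with plain CE; report held-out accuracy.

    10% of source images (all four of their rotations) are held out to
    measure pretext accuracy; the remaining 90% train.
    """
    if spec.n_outputs != 4 or spec.head != "linear":
        raise ValueError("pretext phase requires n_outputs=4 and a linear head")
    shapes = {s.pixel_data.shape for s in rotation_data}
    if any(sh[0] != sh[1] for sh in shapes) or len(shapes) != 1:
        raise ValueError("rotation samples must all be square and uniformly sized")
    rng = np.random.default_rng(config.seed)

    ids = list(dict.fromkeys(s.source_image_id for s in rotation_data))
    perm = rng.permutation(len(ids))
    n_hold = max(1, len(ids) // 10)
    held = {ids[i] for i in perm[:n_hold]}
    tr = [s for s in rotation_data if s.source_image_id not in held]
    ho = [s for s in rotation_data if s.source_image_id in held]

    x = np.stack([s.pixel_data for s in tr]).astype(np.float32)
    y = np.array([s.rotation_label for s in tr])
    model = build_model(spec)
    opt = SGD([model.backbone.params(), model.head.params()], config.weight_decay)

    def ce_grad(probs, yb):
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(yb)), yb] = 1.0
        return (probs - onehot) / len(yb)

    def ce_val(probs, yb):
        return float(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, 1.0)).mean())

    history = []
    for epoch in range(config.epochs):
        # same LR for both groups in the pretext phase: nothing is pretrained yet
        lr = lr_at(epoch, config, "projection")
        loss = _epoch_pass(model, opt, x, y, ce_grad, ce_val, [lr, lr], config.batch_size, rng)
        history.append({"epoch": epoch, "loss": loss, "lr": lr})

    xh = np.stack([s.pixel_data for s in ho]).astype(np.float32)
    yh = np.array([s.rotation_label for s in ho])
    acc = float((model.predict_proba(xh).argmax(axis=1) == yh).mean())
    return TrainedModel(model=model, spec=spec, config=config, history=history, pretext_accuracy=acc)


def transfer_weights(pretrained: TrainedModel, grading_spec: ModelSpec) -> Model:
    """Copy backbone weights bitwise; initialize a fresh head from the grading spec."""
    if grading_spec.backbone != pretrained.spec.backbone:
        raise ValueError(
            f"backbone mismatch: {grading_spec.backbone!r} vs {pretrained.spec.backbone!r}"
        )
    model = build_model(grading_spec)
    src = pretrained.model.backbone.params()
    dst = model.backbone.params()
    if len(src) != len(dst) or any(a.value.shape != b.value.shape for a, b in zip(src, dst)):
        raise ValueError("backbone architecture mismatch: parameter shapes differ")
    for a, b in zip(src, dst):
        b.value = a.value.copy()
    return model


def develop(model: Model, cohort: Cohort, config: TrainConfig, spec: Optional[ModelSpec] = None) -> TrainedModel:
    """Train the grading model on a cohort's images (observed labels).

    Images must already be uniformly sized. Augmentation (random quarter-turn
    + horizontal flip) is applied per batch when enabled. The projection and
    backbone parameter groups follow the cosine schedule at their respective
    rates; per-epoch loss and both rates are logged.
    """
    images = cohort.images()
    labels = np.array([img.observed_label for img in images])
    if len(set(labels.tolist())) < 2:
        raise ValueError("development cohort must contain both classes")
    arrays = [_to_3ch(img.pixels) for img in images]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"images must be preprocessed to a uniform size, got {sorted(shapes)}")
    x = np.stack(arrays).astype(np.float32)
    rng = np.random.default_rng(config.seed)
    opt = SGD([model.backbone.params(), model.head.params()], config.weight_decay)
    loss_cfg = config.loss

    def grad(probs, yb):
        return total_weighted_grad_logits(probs, yb, loss_cfg)

    def loss_val(probs, yb):
        return total_weighted_loss(BatchPrediction(probs, yb), loss_cfg)

    aug = augment if config.augment else None
    history = []
    for epoch in range(config.epochs):
        lr_p = lr_at(epoch, config, "projection")
        lr_b = lr_at(epoch, config, "backbone")
        loss = _epoch_pass(
            model, opt, x, labels, grad, loss_val, [lr_b, lr_p], config.batch_size, rng, aug
        )
        history.append({"epoch": epoch, "loss": loss, "lr_projection": lr_p, "lr_backbone": lr_b})
    return TrainedModel(model=model, spec=spec or ModelSpec(), config=config, history=history)


def save_model(trained: TrainedModel, path) -> None:
    """Checkpoint: parameter arrays in an .npz plus a JSON sidecar (spec, config, history)."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    params = trained.model.backbone.params() + trained.model.head.params()
    np.savez(path, **{f"p{i}": p.value for i, p in enumerate(params)})
    sidecar = {
        "spec": dataclasses.asdict(trained.spec),
        "config": dataclasses.asdict(trained.config),
        "history": trained.history,
        "pretext_accuracy": trained.pretext_accuracy,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path) -> TrainedModel:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    spec_d = sidecar["spec"]
    spec_d["backbone_kwargs"] = {
        k: tuple(v) if isinstance(v, list) else v for k, v in spec_d["backbone_kwargs"].items()
    }
    spec = ModelSpec(**spec_d)
    cfg_d = sidecar["config"]
    cfg_d["loss"] = LossConfig(**cfg_d["loss"])
    config = TrainConfig(**cfg_d)
    model = build_model(spec)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as arrs:
        params = model.backbone.params() + model.head.params()
        if len(arrs.files) != len(params):
            raise ValueError("checkpoint parameter count does not match the spec's architecture")
        for i, p in enumerate(params):
            p.value = arrs[f"p{i}"].astype(np.float32)
    return TrainedModel(
        model=model,
        spec=spec,
        config=config,
        history=sidecar["history"],
        pretext_accuracy=sidecar.get("pretext_accuracy"),
    )
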