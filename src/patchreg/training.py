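"""Training orchestration: pretraining, self-feedback fine-tuning, and the
coarse-to-fine (level-1 -> level-2) pipeline.

The self-feedback pass predicts every training volume with the current
model, maps prediction errors, histograms them into integer bins,
allocates an extra-sample budget inversely to bin frequency, extracts
the new patches, and fine-tunes on old + new samples.  Level 2 trains a
fresh model on the residual deformations left after applying level-1
predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from patchreg import nn
from patchreg._residual import solve_residual
from patchreg.deform import distance_map, warp
from patchreg.network import NetworkConfig, PatchModel, build_model
from patchreg.predict import predict_field
from patchreg.sampling import (
    allocate_samples,
    build_training_set,
    distance_histogram,
    draw_feedback_centers,
    extract_patch_pair,
)

logger = logging.getLogger(__name__)

__all__ = ["FeedbackConfig", "TrainConfig", "LevelModels", "pretrain",
           "continue_training", "self_feedback_finetune", "train_level2"]


@dataclass
class FeedbackConfig:
    """Self-feedback stage parameters."""

    alpha: float = 1.0 / 32.0
    extra_per_volume: int = 2000
    feedback_step: int = 48
    retain_old: bool = True
    enabled: bool = True

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.extra_per_volume < 0:
            raise ValueError("extra_per_volume must be >= 0")


@dataclass
class TrainConfig:
    """Optimization and sampling parameters for one training stage."""

    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    step: int = 32
    samples_per_epoch: int | None = None
    augment_factors: tuple = (1.0,)
    level2_augment: tuple = (1.0, 0.5)
    smooth_radius: int = 1
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.step < 1:
            raise ValueError("epochs, batch_size and step must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class LevelModels:
    """The coarse (level-1) and fine (level-2) models of one pipeline."""

    level1: PatchModel
    level2: PatchModel

    def __post_init__(self):
        c1, c2 = self.level1.cfg, self.level2.cfg
        if (c1.window, c1.output) != (c2.window, c2.output):
            raise ValueError("both levels must share window/output sizes")


def _stack_samples(samples):
    F = np.stack([s.fixed_patch for s in samples])
    M = np.stack([s.moving_patch for s in samples])
    T = np.stack([s.target for s in samples])
    return F, M, T


def _fit(model: PatchModel, samples, cfg: TrainConfig, val_samples=None):
    """Shared epoch loop.  Deterministic for a given (model, data, seed)."""
    if not samples:
        raise ValueError("training sample set is empty")
    rng = np.random.default_rng(cfg.seed)
    model.dropout.rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params(), model.grads(), lr=cfg.learning_rate)
    F, M, T = _stack_samples(samples)
    val = _stack_samples(val_samples) if val_samples else None
    history = {"train": [], "val": []}
    n = len(samples)
    per_epoch = min(cfg.samples_per_epoch or n, n)
    for epoch in range(cfg.epochs):
        # optionally train each epoch on a fresh random subset of a larger
        # sample pool: more position diversity at fixed epoch cost
        perm = rng.permutation(n)[:per_epoch]
        losses = []
        for i in range(0, per_epoch, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(F[idx], M[idx], train=True)
            loss, grad = nn.l1_loss_and_grad(pred, T[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train"].append(float(np.mean(losses)))
        if val is not None:
            history["val"].append(evaluate_loss(model, val_samples))
        logger.info("epoch %d/%d train %.4f%s", epoch + 1, cfg.epochs,
                    history["train"][-1],
                    f" val {history['val'][-1]:.4f}" if val is not None else "")
    return history


def evaluate_loss(model: PatchModel, samples, batch_size: int = 64) -> float:
    """Inference-mode mean L1 loss over a sample list."""
    F, M, T = _stack_samples(samples)
    total, count = 0.0, 0
    for i in range(0, len(samples), batch_size):
        pred = model.forward(F[i:i + batch_size], M[i:i + batch_size], train=False)
        loss, _ = nn.l1_loss_and_grad(pred, T[i:i + batch_size])
        total += loss * len(pred)
        count += len(pred)
    return total / count


def pretrain(samples, net_cfg: NetworkConfig, cfg: TrainConfig, val_samples=None):
    """Train a fresh model on fixed-grid samples; returns (model, history)."""
    model = build_model(net_cfg)
    history = _fit(model, samples, cfg, val_samples)
    return model, history


def continue_training(model: PatchModel, samples, cfg: TrainConfig, val_samples=None):
    """Fine-tune a copy of ``model`` on ``samples`` (no feedback pass)."""
    out = model.copy()
    history = _fit(out, samples, cfg, val_samples)
    return out, history


def _mask_border(dmap, margin: int):
    """Zero the error map where no ``margin``-sized window fits.

    Border voxels can never become patch centers, so their errors must not
    enter the feedback histogram (they would allocate undrawable samples).
    """
    from patchreg.deform import DistanceMap

    lo = margin // 2
    hi = margin - lo
    vals = np.zeros_like(dmap.values)
    sl = tuple(slice(lo, n - hi + 1) for n in dmap.values.shape)
    vals[sl] = dmap.values[sl]
    return DistanceMap(values=vals)


def _volume_triples(volumes):
    for v in volumes:
        if isinstance(v, dict):
            yield v["fixed"], v["moving"], v["gt_field"]
        else:
            yield v


def self_feedback_finetune(model: PatchModel, volumes, old_samples, cfg: TrainConfig,
                           val_samples=None):
    """Feedback pass + fine-tuning; returns (model, report).

    With a zero extra-sample budget and ``retain_old`` the resulting
    training run is identical to :func:`continue_training`.
    """
    fb = cfg.feedback
    w, o = model.cfg.window, model.cfg.output
    rng = np.random.default_rng(cfg.seed + 7919)
    new_samples = []
    report = {"volumes": [], "alpha": fb.alpha, "extra_per_volume": fb.extra_per_volume}
    for vi, (fixed, moving, gt) in enumerate(_volume_triples(volumes)):
        P = predict_field(model, fixed, moving, smooth_radius=cfg.smooth_radius)
        dmap = distance_map(gt, P)
        dmap = _mask_border(dmap, w)  # histogram only window-eligible voxels
        hist = distance_histogram(dmap)
        entry = {"volume": vi, "n_per_bin": hist.n_per_bin.tolist()}
        if hist.n_bins == 0 or fb.extra_per_volume == 0:
            entry["s_per_bin"] = []
            if hist.n_bins == 0:
                logger.info("volume %d: all errors round to 0; no feedback bins", vi)
            report["volumes"].append(entry)
            continue
        alloc = allocate_samples(hist.n_per_bin, fb.alpha, fb.extra_per_volume)
        centers = draw_feedback_centers(dmap, alloc, margin=w, seed=rng)
        entry["s_per_bin"] = alloc.s_per_bin.tolist()
        report["volumes"].append(entry)
        for c in centers:
            new_samples.append(extract_patch_pair(fixed, moving, gt, c, w, o))
    samples = list(old_samples) + new_samples if fb.retain_old else new_samples
    report["n_old"] = len(old_samples)
    report["n_new"] = len(new_samples)
    if val_samples:
        report["val_loss_before"] = evaluate_loss(model, val_samples)
    out = model.copy()
    history = _fit(out, samples, cfg, val_samples)
    report["history"] = history
    if val_samples:
        report["val_loss_after"] = evaluate_loss(out, val_samples)
    return out, report


def train_level2(level1: PatchModel, volumes2, net_cfg: NetworkConfig, cfg: TrainConfig,
                 val_samples=None):
    """Train the fine-stage model on level-1 residual deformations.

    Each moving volume is warped by the level-1 prediction; the residual
    field that maps the warped volume onto the fixed one (solved from the
    known ground truth and the prediction) becomes the level-2 target.
    Samples are augmented with ``cfg.level2_augment`` factors, and a
    self-feedback pass runs when enabled.
    """
    residual_pairs = []
    for fixed, moving, gt in _volume_triples(volumes2):
        P = predict_field(level1, fixed, moving, smooth_radius=cfg.smooth_radius)
        m1 = warp(moving, P)
        r = solve_residual(gt, P)
        residual_pairs.append((fixed, m1, r))
    w, o = net_cfg.window, net_cfg.output
    samples = build_training_set(residual_pairs, w, o, cfg.step,
                                 augment_factors=cfg.level2_augment)
    model, history = pretrain(samples, net_cfg, cfg, val_samples)
    report = {"pretrain_history": history, "n_samples": len(samples)}
    if cfg.feedback.enabled and cfg.feedback.extra_per_volume > 0:
        model, fb_report = self_feedback_finetune(model, residual_pairs, samples, cfg,
                                                 val_samples)
        report["feedback"] = fb_report
    return model, report
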