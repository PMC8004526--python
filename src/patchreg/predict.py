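"""Dense field prediction by sliding-window inference with overlap averaging.

A ``w^3`` window traverses the (replicate-padded) fixed/moving pair at
stride ``o``; each predicted central ``o^3`` block is summed into a
running field accumulator while a parallel counter records per-voxel
superpositions; the assembled field is the element-wise quotient,
cropped back and mean-filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from patchreg.deform import DisplacementField, mean_filter_field, warp
from patchreg.volumes_io import Volume3D

logger = logging.getLogger(__name__)

__all__ = ["AccumulatorPair", "predict_field", "register", "pad_amount",
           "superposition_counts"]


@dataclass
class AccumulatorPair:
    """Running displacement sums and per-voxel superposition counts."""

    phi_temp: np.ndarray  # (Z, Y, X, 3)
    W: np.ndarray  # (Z, Y, X), integer-valued

    def resolve(self) -> np.ndarray:
        """phi = phi_temp / W where covered; zero where W == 0."""
        out = np.zeros_like(self.phi_temp)
        covered = self.W > 0
        out[covered] = self.phi_temp[covered] / self.W[covered, None]
        return out


def pad_amount(w: int, o: int) -> int:
    """Replicate-padding needed so central blocks cover every voxel."""
    return int(np.ceil((w - o) / 2))


def _starts(L: int, w: int, stride: int) -> list:
    if w > L:
        raise ValueError(f"window {w} exceeds axis length {L}")
    starts = list(range(0, L - w + 1, stride))
    if (L - w) % stride != 0:
        starts.append(L - w)
    return starts


def _window_grid(shape, w, o):
    pad = pad_amount(w, o)
    padded = tuple(s + 2 * pad for s in shape)
    per_axis = [_starts(L, w, o) for L in padded]
    starts = [(a, b, c) for a in per_axis[0] for b in per_axis[1] for c in per_axis[2]]
    return pad, padded, starts


def superposition_counts(shape, w: int, o: int) -> np.ndarray:
    """The W counter for a given geometry (model-independent)."""
    pad, padded, starts = _window_grid(shape, w, o)
    W = np.zeros(padded, dtype=np.int32)
    off = w // 2 - o // 2
    for s in starts:
        W[s[0] + off:s[0] + off + o, s[1] + off:s[1] + off + o,
          s[2] + off:s[2] + off + o] += 1
    sl = tuple(slice(pad, pad + n) for n in shape)
    return W[sl]


def predict_field(model, fixed: Volume3D, moving: Volume3D, w: int | None = None,
                  o: int | None = None, smooth_radius: int = 1, batch_size: int = 64,
                  with_report: bool = False):
    """Assemble the dense displacement field for a volume pair.

    ``model`` is either a trained :class:`~patchreg.network.PatchModel` or
    any object exposing ``forward(fixed_batch, moving_batch)`` (plus
    optionally ``predict_blocks(fb, mb, centers)`` receiving unpadded
    center coordinates, used by assembly oracles).  Window/output sizes
    default to the model config.
    """
    if fixed.data.shape != moving.data.shape:
        raise ValueError("fixed and moving volumes must share a shape")
    cfg = getattr(model, "cfg", None)
    if w is None or o is None:
        if cfg is None:
            raise ValueError("w and o are required for models without a config")
        w = cfg.window if w is None else w
        o = cfg.output if o is None else o
    if cfg is not None and (cfg.window != w or cfg.output != o):
        raise ValueError(
            f"model expects window {cfg.window}/output {cfg.output}, got {w}/{o}"
        )
    shape = fixed.data.shape
    pad, padded, starts = _window_grid(shape, w, o)
    fpad = np.pad(np.asarray(fixed.data, dtype=np.float32), pad, mode="edge")
    mpad = np.pad(np.asarray(moving.data, dtype=np.float32), pad, mode="edge")
    acc = AccumulatorPair(
        phi_temp=np.zeros(padded + (3,), dtype=np.float64),
        W=np.zeros(padded, dtype=np.int32),
    )
    off = w // 2 - o // 2  # central block offset inside a window
    use_centers = hasattr(model, "predict_blocks")
    for i in range(0, len(starts), batch_size):
        chunk = starts[i:i + batch_size]
        fb = np.stack([fpad[s[0]:s[0] + w, s[1]:s[1] + w, s[2]:s[2] + w] for s in chunk])
        mb = np.stack([mpad[s[0]:s[0] + w, s[1]:s[1] + w, s[2]:s[2] + w] for s in chunk])
        if use_centers:
            centers = [tuple(s[a] + w // 2 - pad for a in range(3)) for s in chunk]
            preds = np.asarray(model.predict_blocks(fb, mb, centers))
        else:
            preds = np.asarray(model.forward(fb, mb))
        if preds.shape != (len(chunk), 3, o, o, o):
            raise ValueError(f"model returned blocks of shape {preds.shape}")
        for s, blk in zip(chunk, preds):
            sl = tuple(slice(s[a] + off, s[a] + off + o) for a in range(3))
            acc.phi_temp[sl] += np.moveaxis(blk, 0, -1)
            acc.W[sl] += 1
    crop = tuple(slice(pad, pad + n) for n in shape)
    raw = acc.resolve()[crop]
    field = DisplacementField(vectors=raw, spacing=fixed.spacing)
    smoothed = mean_filter_field(field, smooth_radius) if smooth_radius > 0 else field
    if not with_report:
        return smoothed
    Wc = acc.W[crop]
    report = {
        "n_windows": len(starts),
        "coverage": float(np.mean(Wc > 0)),
        "W_min": int(Wc.min()),
        "W_max": int(Wc.max()),
        "W_mean": float(Wc.mean()),
    }
    return smoothed, report


@dataclass
class RegistrationResult:
    warped: Volume3D
    field_level1: DisplacementField
    field_level2: DisplacementField
    intermediate: Volume3D


def register(models, moving: Volume3D, fixed: Volume3D, smooth_radius: int = 1,
             batch_size: int = 64) -> RegistrationResult:
    """Two-level registration: coarse field, warp, fine field, warp.

    ``models`` needs ``level1`` and ``level2`` attributes (either may be a
    stub with the prediction protocol of :func:`predict_field`).  The
    final volume is produced by sequential warping; a single-resampling
    composite is available via :func:`patchreg.deform.compose_fields`.
    """
    f1 = predict_field(models.level1, fixed, moving, smooth_radius=smooth_radius,
                       batch_size=batch_size)
    m1 = warp(moving, f1)
    f2 = predict_field(models.level2, fixed, m1, smooth_radius=smooth_radius,
                       batch_size=batch_size)
    m2 = warp(m1, f2)
    return RegistrationResult(warped=m2, field_level1=f1, field_level2=f2, intermediate=m1)
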