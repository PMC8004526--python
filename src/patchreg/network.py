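"""Dual-branch 3D patch regression network.

Two ``w^3`` patches (fixed, moving) each pass through an InputConv unit
(5^3 conv, stride 1, pad 2, PReLU) and ``n_encoders`` Encoder units
(3^3 conv pad 1, PReLU, 3^3/stride-2 pooling), with feature maps doubling
per Encoder and spatial size halving.  Branch features are concatenated
(dropout applied there), then three independent component heads (x, y, z)
each run three Decoder units (same structure as an Encoder, widths
continuing to double) and an OutConn dense layer producing a flattened
``o^3`` displacement block, reshaped to ``(o, o, o)``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np

from patchreg import nn

__all__ = ["NetworkConfig", "PatchModel", "build_model", "forward", "l1_loss",
           "save_model", "load_model"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters for one patch model."""

    window: int = 64
    output: int = 9
    base_features: int = 4
    n_encoders: int = 3
    n_decoders: int = 3
    dropout_rate: float = 0.5
    pooling: str = "max"
    seed: int = 0

    def __post_init__(self):
        if self.window < 2 or self.output < 1 or self.output >= self.window:
            raise ValueError("require 1 <= output < window")
        if self.pooling not in ("max", "avg"):
            raise ValueError("pooling must be 'max' or 'avg'")
        if self.window // 2 ** self.n_encoders < 1:
            raise ValueError(
                f"window {self.window} underflows after {self.n_encoders} encoder halvings"
            )

    @property
    def concat_features(self) -> int:
        return 2 * self.base_features * 2 ** self.n_encoders

    @property
    def encoder_spatial(self) -> int:
        n = self.window
        for _ in range(self.n_encoders):
            n = -(-n // 2)  # pooling output is ceil(n/2), floored at 1
        return n

    @property
    def final_spatial(self) -> int:
        n = self.encoder_spatial
        for _ in range(self.n_decoders):
            n = -(-n // 2)
        return n


def _encoder_unit(in_ch, out_ch, rng, pooling="max"):
    pool = nn.MaxPool3d() if pooling == "max" else nn.AvgPool3d()
    return [nn.Conv3d(in_ch, out_ch, 3, 1, rng), nn.PReLU(), pool]


class PatchModel:
    """Learned parameters + computation graph for one network level."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_features
        self.branches = []
        for _ in range(2):  # fixed branch, moving branch
            # gradients w.r.t. the raw input patches are never needed
            layers = [nn.Conv3d(1, f, 5, 2, rng, need_input_grad=False), nn.PReLU()]
            ch = f
            for _ in range(cfg.n_encoders):
                layers += _encoder_unit(ch, 2 * ch, rng, cfg.pooling)
                ch *= 2
            self.branches.append(layers)
        self.dropout = nn.Dropout(cfg.dropout_rate)
        cc = cfg.concat_features
        self.heads = []
        for _ in range(3):  # x, y, z displacement components
            layers = []
            ch = cc
            for _ in range(cfg.n_decoders):
                layers += _encoder_unit(ch, 2 * ch, rng, cfg.pooling)
                ch *= 2
            layers.append(nn.Linear(ch * cfg.final_spatial ** 3, cfg.output ** 3, rng))
            self.heads.append(layers)

    # -- parameter plumbing ------------------------------------------------
    def _all_layers(self):
        for branch in self.branches:
            yield from branch
        yield self.dropout
        for head in self.heads:
            yield from head

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def grads(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.grads())
        return out

    def copy(self) -> "PatchModel":
        return copy.deepcopy(self)

    # -- computation -------------------------------------------------------
    def _check_patches(self, fixed, moving):
        w = self.cfg.window
        fixed = np.asarray(fixed, dtype=np.float32)
        moving = np.asarray(moving, dtype=np.float32)
        squeeze = fixed.ndim == 3
        if squeeze:
            fixed, moving = fixed[None], moving[None]
        if fixed.shape[1:] != (w, w, w) or moving.shape != fixed.shape:
            raise ValueError(f"patches must be (B, {w}, {w}, {w}); got {fixed.shape}")
        return fixed[:, None], moving[:, None], squeeze

    def forward(self, fixed, moving, train: bool = False) -> np.ndarray:
        """Predict ``(B, 3, o, o, o)`` displacement blocks (or (3, o, o, o))."""
        fixed, moving, squeeze = self._check_patches(fixed, moving)
        o = self.cfg.output
        feats = []
        for x, layers in zip((fixed, moving), self.branches):
            for layer in layers:
                x = layer.forward(x, train)
            feats.append(x)
        z = np.concatenate(feats, axis=1)
        z = self.dropout.forward(z, train)
        self._concat_shape = z.shape
        B = z.shape[0]
        outs = []
        self._head_pre_flat = []
        for layers in self.heads:
            h = z
            for layer in layers[:-1]:
                h = layer.forward(h, train)
            self._head_pre_flat.append(h.shape)
            h = layers[-1].forward(h.reshape(B, -1), train)
            outs.append(h.reshape(B, o, o, o))
        y = np.stack(outs, axis=1)
        return y[0] if squeeze else y

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        if gy.ndim == 4:
            gy = gy[None]
        B = gy.shape[0]
        gz = np.zeros(self._concat_shape, dtype=np.float32)
        for c, layers in enumerate(self.heads):
            g = layers[-1].backward(gy[:, c].reshape(B, -1))
            g = g.reshape(self._head_pre_flat[c])
            for layer in reversed(layers[:-1]):
                g = layer.backward(g)
            gz += g
        gz = self.dropout.backward(gz)
        half = self.cfg.concat_features // 2
        for i, layers in enumerate(self.branches):
            g = np.ascontiguousarray(gz[:, i * half:(i + 1) * half])
            for layer in reversed(layers):
                g = layer.backward(g)


def build_model(cfg: NetworkConfig) -> PatchModel:
    """Instantiate a model; the same config seed gives identical init."""
    return PatchModel(cfg)


def forward(model: PatchModel, fixed_patch, moving_patch) -> np.ndarray:
    """Inference-mode prediction (dropout disabled, deterministic)."""
    return model.forward(fixed_patch, moving_patch, train=False)


def l1_loss(pred, target) -> float:
    """Mean absolute difference over all entries of the blocks."""
    loss, _ = nn.l1_loss_and_grad(np.asarray(pred), np.asarray(target))
    return loss


def save_model(model: PatchModel, path: str) -> None:
    """Checkpoint: architecture config + every parameter array."""
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    with open(path, "wb") as fh:
        np.savez(fh, config=json.dumps(asdict(model.cfg)), **arrays)


def load_model(path: str) -> PatchModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = NetworkConfig(**json.loads(str(data["config"])))
        model = PatchModel(cfg)
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model
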