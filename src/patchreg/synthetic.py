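"""Synthetic phantoms, region labels, and smooth ground-truth fields.

Generates a desk-scale analogue of a pre-aligned brain registration
corpus: a fixed textured nested-ellipsoid phantom with labeled
substructures, per-sample smooth invertible displacement fields, and
moving images derived by warping the phantom with the numerically
inverted field (so the sampled field is the exact registration target).
Three groups are produced: large-deformation training pairs, composed
large+small pairs whose coarse-stage residual is small, and validation
pairs mirroring the latter.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from patchreg._residual import invert_field
from patchreg.deform import (
    DisplacementField,
    compose_fields,
    jacobian_determinant,
    warp,
    warp_labels,
)
from patchreg.volumes_io import (
    LabelVolume,
    Volume3D,
    write_field,
    write_labels,
    write_volume,
    read_volume,
    read_labels,
    read_field,
)

__all__ = ["PhantomSpec", "FieldSpec", "make_phantom", "make_smooth_field",
           "make_corpus", "make_dataset", "load_dataset"]


@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    n_regions: int = 4
    texture_scale: float = 2.5
    texture_amplitude: float = 0.12
    gradient_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if min(self.shape) < 16:
            raise ValueError("phantom axes must be >= 16 voxels")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")


@dataclass
class FieldSpec:
    max_magnitude: float = 6.0
    smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.max_magnitude < 0 or self.smoothness <= 0:
            raise ValueError("invalid field spec")


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    acc = np.zeros(shape)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec):
    """Textured nested-ellipsoid phantom with ``n_regions`` labeled parts.

    Returns ``(Volume3D, LabelVolume)``; intensities lie in [0, 1], label
    0 is background and labels 1..n_regions are all present.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = tuple(s / 2 for s in shape)
    brain_semi = tuple(0.42 * s for s in shape)
    brain = _ellipsoid_mask(shape, center, brain_semi)

    labels = np.zeros(shape, dtype=np.int32)
    intensity = np.where(brain, 0.35, 0.02)
    for rid in range(1, spec.n_regions + 1):
        for _ in range(60):  # rejection sampling; keep every label populated
            c = [center[a] + (rng.uniform(-0.55, 0.55)) * brain_semi[a] for a in range(3)]
            semi = [rng.uniform(0.12, 0.22) * shape[a] for a in range(3)]
            mask = _ellipsoid_mask(shape, c, semi) & brain
            trial = labels.copy()
            trial[mask] = rid
            counts = np.bincount(trial.ravel(), minlength=rid + 1)
            if mask.sum() >= 27 and (counts[1:rid + 1] >= 27).all():
                labels = trial
                level = 0.45 + 0.5 * (rid / spec.n_regions)
                intensity = np.where(mask, level, intensity)
                break
        else:
            raise RuntimeError(f"could not place region {rid}")
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), spec.texture_scale)
    texture /= max(np.abs(texture).max(), 1e-12)
    intensity = intensity + spec.texture_amplitude * texture * brain
    # smooth intensity ramps make locations globally identifiable, like
    # the large-scale cytoarchitectonic gradients of a real brain
    if spec.gradient_strength > 0:
        gs = spec.gradient_strength
        grids = np.indices(shape, dtype=np.float64)
        ramp = sum(w * (2.0 * g / (n - 1) - 1.0)
                   for w, g, n in zip((0.8, 1.0, 1.2), grids, shape))
        ramp /= np.abs(ramp).max()
        intensity = intensity + gs * ramp * brain
    intensity = np.clip(intensity, 0.0, 1.0)
    return Volume3D(data=intensity), LabelVolume(labels=labels)


def make_smooth_field(shape, spec: FieldSpec) -> DisplacementField:
    """Gaussian-smoothed noise field rescaled to a peak vector norm.

    The construction is checked to be fold-free (no non-positive Jacobian
    determinants); a magnitude/smoothness combination that folds is a
    contract error.
    """
    shape = tuple(int(s) for s in shape)
    if spec.max_magnitude == 0:
        return DisplacementField(vectors=np.zeros(shape + (3,), dtype=np.float32))
    rng = np.random.default_rng(spec.seed)
    vec = np.empty(shape + (3,), dtype=np.float64)
    for c in range(3):
        vec[..., c] = ndimage.gaussian_filter(rng.standard_normal(shape), spec.smoothness)
    norms = np.sqrt((vec ** 2).sum(axis=-1))
    peak = norms.max()
    if peak <= 0:
        raise ValueError("degenerate noise field")
    vec *= spec.max_magnitude / peak
    field = DisplacementField(vectors=vec)
    det = jacobian_determinant(field).det
    if (det <= 0).any():
        raise ValueError(
            f"field folds (max_magnitude={spec.max_magnitude}, "
            f"smoothness={spec.smoothness}); increase smoothness"
        )
    return field


def _perturb_intensity(data: np.ndarray, rng: np.random.Generator,
                       gamma_jitter: float = 0.1, noise_sd: float = 0.01) -> np.ndarray:
    gamma = rng.uniform(1.0 - gamma_jitter, 1.0 + gamma_jitter)
    out = np.clip(data, 0.0, 1.0) ** gamma + noise_sd * rng.standard_normal(data.shape)
    return np.clip(out, 0.0, 1.0)


def _make_sample(fixed, labels, phi, rng):
    """Moving image whose exact registration target onto ``fixed`` is ``phi``."""
    g = invert_field(phi)
    moving = warp(fixed, g)
    moving = Volume3D(data=_perturb_intensity(moving.data, rng), spacing=moving.spacing)
    labels_moving = warp_labels(labels, g)
    return moving, labels_moving


def make_corpus(n_train1: int, n_train2: int, n_val: int,
                phantom: PhantomSpec = None, large: FieldSpec = None,
                small: FieldSpec = None, seed: int = 0,
                confine_fields: bool = True) -> dict:
    """In-memory corpus: {'train1': [...], 'train2': [...], 'val': [...]}.

    Each sample is a dict with keys fixed, moving, gt_field, labels_fixed,
    labels_moving, kind.  ``train1`` uses large fields; ``train2`` and
    ``val`` compose a large and a small field so the coarse-stage residual
    is small.  With ``confine_fields`` (default) deformations are feathered
    to the tissue envelope, as in pre-aligned data where background does
    not deform; without it fields extend over the whole lattice.
    """
    phantom = phantom or PhantomSpec()
    large = large or FieldSpec(max_magnitude=6.0, smoothness=8.0)
    small = small or FieldSpec(max_magnitude=2.0, smoothness=6.0)
    if large.max_magnitude <= small.max_magnitude:
        raise ValueError("large fields must exceed small fields in magnitude")
    from dataclasses import replace as _dc_replace

    rng = np.random.default_rng(seed)
    fixed, labels = make_phantom(
        _dc_replace(phantom, seed=int(rng.integers(2 ** 31)))
    )
    # deformation support: confined to tissue (background does not deform
    # in pre-aligned data, and featureless background displacement would
    # be unobservable anyway); smoothly feathered to stay fold-free
    support = ndimage.gaussian_filter((fixed.data > 0.15).astype(np.float64), 5.0)
    support /= max(support.max(), 1e-12)

    def _confine(field):
        vec = field.vectors * support[..., None]
        for _ in range(10):
            cand = DisplacementField(vectors=vec)
            if (jacobian_determinant(cand).det > 0).all():
                return cand
            vec = vec * 0.9
        raise RuntimeError("could not produce a fold-free confined field")

    corpus = {"train1": [], "train2": [], "val": []}
    plan = [("train1", n_train1), ("train2", n_train2), ("val", n_val)]
    for kind, count in plan:
        for _ in range(count):
            lspec = FieldSpec(large.max_magnitude, large.smoothness,
                              seed=int(rng.integers(2 ** 31)))
            phi = make_smooth_field(phantom.shape, lspec)
            if kind != "train1":
                sspec = FieldSpec(small.max_magnitude, small.smoothness,
                                  seed=int(rng.integers(2 ** 31)))
                phi = compose_fields(phi, make_smooth_field(phantom.shape, sspec))
            if confine_fields:
                phi = _confine(phi)
            moving, labels_moving = _make_sample(fixed, labels, phi, rng)
            corpus[kind].append({
                "fixed": fixed,
                "moving": moving,
                "gt_field": phi,
                "labels_fixed": labels,
                "labels_moving": labels_moving,
                "kind": kind,
            })
    return corpus


def make_dataset(n_train1: int, n_train2: int, n_val: int, out_dir: str,
                 phantom: PhantomSpec = None, large: FieldSpec = None,
                 small: FieldSpec = None, seed: int = 0) -> dict:
    """Generate a corpus and write it to ``out_dir`` with a manifest."""
    phantom = phantom or PhantomSpec()
    large = large or FieldSpec(max_magnitude=6.0, smoothness=8.0)
    small = small or FieldSpec(max_magnitude=2.0, smoothness=6.0)
    corpus = make_corpus(n_train1, n_train2, n_val, phantom, large, small, seed)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "seed": seed,
        "phantom": asdict(phantom),
        "large_field": asdict(large),
        "small_field": asdict(small),
        "samples": [],
    }
    idx = 0
    for kind in ("train1", "train2", "val"):
        for sample in corpus[kind]:
            name = f"{kind}_{idx:03d}"
            sdir = os.path.join(out_dir, name)
            os.makedirs(sdir, exist_ok=True)
            write_volume(sample["fixed"], os.path.join(sdir, "fixed.nii.gz"))
            write_volume(sample["moving"], os.path.join(sdir, "moving.nii.gz"))
            write_field(sample["gt_field"], os.path.join(sdir, "gt_field.nii.gz"))
            write_labels(sample["labels_fixed"], os.path.join(sdir, "labels_fixed.nii.gz"))
            write_labels(sample["labels_moving"], os.path.join(sdir, "labels_moving.nii.gz"))
            manifest["samples"].append({"dir": name, "kind": kind})
            idx += 1
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_dataset(out_dir: str) -> dict:
    """Read a written corpus back into the in-memory layout."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    corpus = {"train1": [], "train2": [], "val": []}
    for entry in manifest["samples"]:
        sdir = os.path.join(out_dir, entry["dir"])
        corpus[entry["kind"]].append({
            "fixed": read_volume(os.path.join(sdir, "fixed.nii.gz")),
            "moving": read_volume(os.path.join(sdir, "moving.nii.gz")),
            "gt_field": read_field(os.path.join(sdir, "gt_field.nii.gz")),
            "labels_fixed": read_labels(os.path.join(sdir, "labels_fixed.nii.gz")),
            "labels_moving": read_labels(os.path.join(sdir, "labels_moving.nii.gz")),
            "kind": entry["kind"],
        })
    return corpus
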