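"""Training-sample construction.

Two sample sources feed training: a fixed-step grid of patch pairs, and a
self-feedback pass that histograms prediction errors and allocates extra
patches inversely to error-bin frequency with a tunable exponent alpha
(small alpha flattens the allocation toward equal per-bin counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from patchreg.deform import DisplacementField, DistanceMap, scale_field, warp
from patchreg.volumes_io import Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "PatchPair",
    "SampleAllocation",
    "grid_centers",
    "extract_patch_pair",
    "distance_histogram",
    "allocate_samples",
    "draw_feedback_centers",
    "build_training_set",
]

VALID_WINDOWS = (16, 32, 64)
VALID_OUTPUTS = (3, 5, 9)


@dataclass
class PatchPair:
    """Co-located fixed/moving windows plus the central GT displacement block.

    ``fixed_patch`` / ``moving_patch`` are ``w^3`` intensity blocks;
    ``target`` has shape ``(3, o, o, o)`` with channel order (ux, uy, uz)
    in voxel units; ``center`` is the (z, y, x) lattice coordinate of the
    shared block center.
    """

    fixed_patch: np.ndarray
    moving_patch: np.ndarray
    target: np.ndarray
    center: tuple

    def __post_init__(self):
        w = self.fixed_patch.shape[0]
        if self.fixed_patch.shape != (w, w, w) or self.moving_patch.shape != (w, w, w):
            raise ValueError("patches must be cubic and equally sized")
        if self.target.ndim != 4 or self.target.shape[0] != 3:
            raise ValueError("target must have shape (3, o, o, o)")
        o = self.target.shape[1]
        if self.target.shape != (3, o, o, o):
            raise ValueError("target block must be cubic")
        if o >= w:
            raise ValueError(f"output size {o} must be smaller than window {w}")


@dataclass
class SampleAllocation:
    """Per-error-bin counts N(i) and allocated extra-sample counts S(i).

    Index ``i - 1`` of each array corresponds to integer error bin ``i``
    (bin 1 .. n); voxels whose error rounds to 0 are never binned.
    """

    n_per_bin: np.ndarray
    s_per_bin: np.ndarray = None
    alpha: float = 0.5
    total_extra: int = 0

    def __post_init__(self):
        self.n_per_bin = np.asarray(self.n_per_bin, dtype=np.int64)
        if self.s_per_bin is None:
            self.s_per_bin = np.zeros_like(self.n_per_bin)
        self.s_per_bin = np.asarray(self.s_per_bin, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.n_per_bin)


def _axis_starts(L: int, w: int, s: int) -> list:
    if w > L:
        raise ValueError(f"window {w} exceeds axis length {L}")
    starts = list(range(0, L - w + 1, s))
    if (L - w) % s != 0:
        starts.append(L - w)  # end-aligned extra window
    return starts


def grid_centers(shape, window: int, step: int) -> list:
    """Centers of a fixed-step window tiling, end-aligned per axis.

    Per axis the window start positions are the multiples of ``step`` in
    ``[0, L - w]`` (count ``floor((L - w)/s) + 1``) plus one end-aligned
    start at ``L - w`` when ``L - w`` is not a multiple of ``step``;
    centers are ``start + w // 2``.  The windows cover every voxel of
    ``[0, L)`` whenever ``step <= window``.
    """
    w, s = int(window), int(step)
    if s < 1:
        raise ValueError("step must be >= 1")
    per_axis = [[st + w // 2 for st in _axis_starts(int(L), w, s)] for L in shape]
    return [(cz, cy, cx) for cz in per_axis[0] for cy in per_axis[1] for cx in per_axis[2]]


def extract_patch_pair(fixed: Volume3D, moving: Volume3D, gt_field: DisplacementField,
                       center, w: int, o: int) -> PatchPair:
    """Cut the co-located ``w^3`` windows and the central ``o^3`` GT block."""
    shape = fixed.data.shape
    if moving.data.shape != shape or gt_field.shape != shape:
        raise ValueError("fixed, moving and gt_field must share a shape")
    wl = [c - w // 2 for c in center]
    ol = [c - o // 2 for c in center]
    for ax in range(3):
        if wl[ax] < 0 or wl[ax] + w > shape[ax]:
            raise ValueError(f"window at center {center} exits the volume on axis {ax}")
        if ol[ax] < wl[ax] or ol[ax] + o > wl[ax] + w:
            raise ValueError("target block exits the window")
    wsl = tuple(slice(l, l + w) for l in wl)
    osl = tuple(slice(l, l + o) for l in ol)
    target = np.moveaxis(gt_field.vectors[osl], -1, 0).copy()
    return PatchPair(
        fixed_patch=np.ascontiguousarray(fixed.data[wsl], dtype=np.float32),
        moving_patch=np.ascontiguousarray(moving.data[wsl], dtype=np.float32),
        target=np.ascontiguousarray(target, dtype=np.float32),
        center=tuple(int(c) for c in center),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(np.int64)


def distance_histogram(dmap: DistanceMap) -> SampleAllocation:
    """Count voxels per integer error bin 1..n (round-half-up binning).

    ``n`` is the maximum rounded error; a map that rounds to zero
    everywhere yields an empty histogram.
    """
    if dmap.values.size == 0:
        raise ValueError("distance map is empty")
    rounded = _round_half_up(dmap.values)
    n = int(rounded.max())
    if n == 0:
        return SampleAllocation(n_per_bin=np.zeros(0, dtype=np.int64))
    counts = np.bincount(rounded.ravel(), minlength=n + 1)[1: n + 1]
    return SampleAllocation(n_per_bin=counts)


def allocate_samples(n_per_bin, alpha: float, A: int) -> SampleAllocation:
    """Allocate ``A`` extra samples across error bins, S(i) ~ (1/N(i))^alpha.

    Weights are normalized over non-zero bins and integerized by
    largest-remainder so that ``sum(S) == A`` exactly.  Empty bins get 0.
    """
    n_per_bin = np.asarray(n_per_bin, dtype=np.int64)
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    A = int(A)
    if A < 0:
        raise ValueError("A must be >= 0")
    nonzero = n_per_bin > 0
    if not nonzero.any():
        raise ValueError("at least one non-zero bin is required")
    weights = np.zeros(len(n_per_bin), dtype=np.float64)
    weights[nonzero] = (1.0 / n_per_bin[nonzero]) ** float(alpha)
    quotas = weights / weights.sum() * A
    s = np.floor(quotas).astype(np.int64)
    shortfall = A - int(s.sum())
    if shortfall > 0:
        remainders = quotas - np.floor(quotas)
        # ties broken toward rarer (higher-weight) bins, then lower index
        order = np.lexsort((np.arange(len(quotas)), -weights, -remainders))
        s[order[:shortfall]] += 1
    return SampleAllocation(n_per_bin=n_per_bin, s_per_bin=s, alpha=float(alpha), total_extra=A)


def draw_feedback_centers(dmap: DistanceMap, alloc: SampleAllocation, margin: int,
                          seed=None) -> list:
    """Sample S(i) voxel centers per error bin, uniformly within the bin.

    Eligible voxels lie at least ``margin // 2`` from the low border and
    ``margin - margin // 2`` from the high border (so a ``margin``-sized
    window around the center fits).  Bins with fewer eligible voxels than
    requested fall back to sampling with replacement (logged).  A bin with
    an allocation but no eligible voxels at all is a contract error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    margin = int(margin)
    lo = margin // 2
    shape = dmap.values.shape
    rounded = _round_half_up(dmap.values)
    inside = np.ones(shape, dtype=bool)
    for ax in range(3):
        idx = np.arange(shape[ax])
        ok = (idx >= lo) & (idx <= shape[ax] - (margin - lo))
        inside &= ok.reshape([-1 if a == ax else 1 for a in range(3)])
    centers = []
    for i in range(1, alloc.n_bins + 1):
        want = int(alloc.s_per_bin[i - 1])
        if want == 0:
            continue
        eligible = np.flatnonzero((rounded == i) & inside)
        if eligible.size == 0:
            raise ValueError(f"no eligible voxels for error bin {i}")
        replace = eligible.size < want
        if replace:
            logger.warning(
                "bin %d: only %d eligible voxels for %d requested; sampling with replacement",
                i, eligible.size, want,
            )
        chosen = rng.choice(eligible, size=want, replace=replace)
        centers.extend(tuple(int(v) for v in np.unravel_index(c, shape)) for c in chosen)
    return centers


def build_training_set(volumes, w: int, o: int, step: int,
                       augment_factors=(1.0,)) -> list:
    """Fixed-grid patch pairs for each (fixed, moving, gt_field) triple.

    For each augmentation factor ``k`` the ground-truth field is scaled by
    ``k`` and the moving image re-derived by warping the fixed image with
    the numerically inverted scaled field, so that the scaled field remains
    the exact registration target.  ``k == 1`` uses the original pair.
    """
    from patchreg._residual import invert_field

    samples = []
    for fixed, moving, gt in volumes:
        centers = grid_centers(fixed.data.shape, w, step)
        for k in augment_factors:
            if k == 1 or k == 1.0:
                mov_k, gt_k = moving, gt
            else:
                gt_k = scale_field(gt, k)
                mov_k = warp(fixed, invert_field(gt_k))
            for c in centers:
                samples.append(extract_patch_pair(fixed, mov_k, gt_k, c, w, o))
    return samples
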