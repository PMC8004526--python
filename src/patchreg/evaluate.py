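"""Quantitative assessment: Dice overlap, endpoint-error statistics,
correlation-plot point export, and Jacobian fold reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from patchreg.deform import DisplacementField, distance_map, jacobian_determinant
from patchreg.volumes_io import LabelVolume

__all__ = ["RegionDiceReport", "dice", "endpoint_error_stats",
           "correlation_points", "jacobian_report"]


@dataclass
class RegionDiceReport:
    """Per-region Dice scores plus a mean +/- SD summary.

    Regions absent from both volumes are reported as ``None`` and excluded
    from the summary.
    """

    per_region: dict
    mean: float
    std: float


def dice(a: LabelVolume, b: LabelVolume, region_ids=None) -> RegionDiceReport:
    """Per-region Dice: 2 |A_r & B_r| / (|A_r| + |B_r|)."""
    if a.labels.shape != b.labels.shape:
        raise ValueError("label volumes must share a shape")
    if region_ids is None:
        region_ids = sorted(set(np.unique(a.labels)) | set(np.unique(b.labels)) - {0})
        region_ids = [int(r) for r in region_ids if r != 0]
    per_region = {}
    defined = []
    for rid in region_ids:
        ma = a.labels == rid
        mb = b.labels == rid
        denom = int(ma.sum()) + int(mb.sum())
        if denom == 0:
            per_region[rid] = None
            continue
        score = 2.0 * int((ma & mb).sum()) / denom
        per_region[rid] = score
        defined.append(score)
    if not defined:
        raise ValueError("no region present in either volume")
    return RegionDiceReport(per_region=per_region, mean=float(np.mean(defined)),
                            std=float(np.std(defined)))


def endpoint_error_stats(G: DisplacementField, P: DisplacementField, mask=None) -> dict:
    """Mean / median / max Euclidean endpoint error, optionally masked."""
    errs = distance_map(G, P).values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != errs.shape:
            raise ValueError("mask shape must match the field lattice")
        errs = errs[mask]
        if errs.size == 0:
            raise ValueError("mask selects no voxels")
    return {
        "mean": float(errs.mean()),
        "median": float(np.median(errs)),
        "max": float(errs.max()),
    }


def correlation_points(G: DisplacementField, P: DisplacementField, n_points: int,
                       seed=None) -> np.ndarray:
    """Seeded (true, predicted) scalar pairs for correlation dot plots.

    Samples voxel/component entries uniformly without replacement; each
    pair is one displacement component at one voxel.
    """
    if G.shape != P.shape:
        raise ValueError("fields must share a lattice")
    total = int(np.prod(G.vectors.shape))
    if n_points > total:
        raise ValueError(f"cannot draw {n_points} points from {total} entries")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(total, size=n_points, replace=False)
    return np.column_stack([G.vectors.reshape(-1)[idx], P.vectors.reshape(-1)[idx]])


def jacobian_report(field: DisplacementField) -> dict:
    """Fold statistics of det(I + grad u) over interior voxels."""
    det = jacobian_determinant(field).det
    n_nonpos = int((det <= 0).sum())
    return {
        "n_interior": int(det.size),
        "n_nonpositive": n_nonpos,
        "fraction_nonpositive": n_nonpos / det.size,
        "min_det": float(det.min()),
        "mean_det": float(det.mean()),
    }
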