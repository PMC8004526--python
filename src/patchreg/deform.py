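"""Displacement-field algebra.

Fields are ``(Z, Y, X, 3)`` float arrays, last axis ``(ux, uy, uz)`` in
voxel units over the fixed-image lattice, pull convention: the warped
value at voxel ``v`` is the moving image sampled at ``v + u(v)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from patchreg.volumes_io import DEFAULT_SPACING_UM, Volume3D

__all__ = [
    "DisplacementField",
    "DistanceMap",
    "JacobianVolume",
    "zero_field",
    "warp",
    "warp_labels",
    "scale_field",
    "compose_fields",
    "mean_filter_field",
    "jacobian_determinant",
    "distance_map",
]

# component c displaces array axis _COMP_AXIS[c]: ux -> x (axis 2), etc.
_COMP_AXIS = (2, 1, 0)


@dataclass
class DisplacementField:
    """Per-voxel 3-vector grid (voxel units) over the fixed lattice."""

    vectors: np.ndarray
    spacing: tuple = (DEFAULT_SPACING_UM,) * 3

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"field requires shape (Z, Y, X, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        """Lattice shape (Z, Y, X)."""
        return self.vectors.shape[:3]


@dataclass
class DistanceMap:
    """Per-voxel Euclidean error between two fields (voxel units)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DistanceMap requires a 3D grid")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class JacobianVolume:
    """Interior-voxel determinants of the mapping Jacobian det(I + grad u)."""

    det: np.ndarray


def zero_field(shape, spacing=(DEFAULT_SPACING_UM,) * 3) -> DisplacementField:
    return DisplacementField(
        vectors=np.zeros(tuple(shape) + (3,), dtype=np.float32), spacing=spacing
    )


def _sample_coords(field: DisplacementField) -> np.ndarray:
    """(3, Z, Y, X) array of sampling coordinates v + u(v), axis order (z, y, x)."""
    shape = field.shape
    grid = np.indices(shape, dtype=np.float64)
    u = field.vectors
    coords = np.empty((3,) + shape, dtype=np.float64)
    coords[0] = grid[0] + u[..., 2]  # z + uz
    coords[1] = grid[1] + u[..., 1]  # y + uy
    coords[2] = grid[2] + u[..., 0]  # x + ux
    return coords


def warp(moving: Volume3D, field: DisplacementField, order: int = 1,
         mode: str = "nearest") -> Volume3D:
    """Trilinearly resample ``moving`` at ``v + u(v)``.

    Out-of-bounds samples use border replication (``mode='nearest'``).
    """
    if field.shape != moving.data.shape:
        raise ValueError(f"field lattice {field.shape} != volume shape {moving.data.shape}")
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64), _sample_coords(field), order=order, mode=mode
    )
    return Volume3D(data=out, spacing=moving.spacing)


def warp_labels(labels, field: DisplacementField):
    """Nearest-neighbour warp for integer region-ID volumes."""
    from patchreg.volumes_io import LabelVolume

    if field.shape != labels.labels.shape:
        raise ValueError("field lattice does not match label volume shape")
    out = ndimage.map_coordinates(labels.labels, _sample_coords(field), order=0, mode="nearest")
    return LabelVolume(labels=out.astype(labels.labels.dtype), spacing=labels.spacing)


def scale_field(field: DisplacementField, k: float) -> DisplacementField:
    """Multiply every displacement vector by the scalar ``k``."""
    if not np.isfinite(k):
        raise ValueError("scale factor must be finite")
    return DisplacementField(vectors=field.vectors * float(k), spacing=field.spacing)


def compose_fields(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Composite field: result(v) = first(v) + second(v + first(v)).

    Warping once with the composite approximates warping sequentially with
    ``first`` then ``second`` (exact up to interpolation error).
    """
    if first.shape != second.shape:
        raise ValueError("fields must share a lattice")
    coords = _sample_coords(first)
    out = first.vectors.astype(np.float64).copy()
    for c in range(3):
        out[..., c] += ndimage.map_coordinates(
            second.vectors[..., c].astype(np.float64), coords, order=1, mode="nearest"
        )
    return DisplacementField(vectors=out, spacing=first.spacing)


def mean_filter_field(field: DisplacementField, radius: int = 1) -> DisplacementField:
    """Box-average each component over a (2*radius+1)^3 neighbourhood.

    Border handling is replication.  ``radius=0`` is the identity.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return DisplacementField(vectors=field.vectors.copy(), spacing=field.spacing)
    size = 2 * radius + 1
    out = np.empty_like(field.vectors, dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.uniform_filter(
            field.vectors[..., c].astype(np.float64), size=size, mode="nearest"
        )
    return DisplacementField(vectors=out, spacing=field.spacing)


def jacobian_determinant(field: DisplacementField) -> JacobianVolume:
    """det(I + grad u) per interior voxel via central differences.

    A positive determinant everywhere indicates a locally invertible,
    orientation-preserving (fold-free) deformation.  Boundary voxels are
    excluded (shape shrinks by 2 per axis).
    """
    shape = field.shape
    if min(shape) < 3:
        raise ValueError("jacobian requires every dimension >= 3")
    u = field.vectors.astype(np.float64)
    # J[c][a] = d u_c / d axis-coordinate of component a
    grads = np.empty((3, 3) + tuple(s - 2 for s in shape))
    interior = (slice(1, -1),) * 3
    for c in range(3):
        for a in range(3):
            g = np.gradient(u[..., c], axis=_COMP_AXIS[a])
            grads[c, a] = g[interior]
    J = grads
    for i in range(3):
        J[i, i] += 1.0
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return JacobianVolume(det=det)


def distance_map(G: DisplacementField, P: DisplacementField) -> DistanceMap:
    """Per-voxel Euclidean norm of G - P."""
    if G.shape != P.shape:
        raise ValueError("fields must share a lattice")
    diff = G.vectors.astype(np.float64) - P.vectors.astype(np.float64)
    return DistanceMap(values=np.sqrt(np.sum(diff * diff, axis=-1)))
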