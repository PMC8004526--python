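"""Fixed-point solvers for residual and inverse displacement fields.

Internal construction utilities (not part of the field-algebra surface):
the synthetic generator needs the inverse of a known field to build a
moving image whose exact registration target is that field, and level-2
training needs the residual field left after applying a level-1
prediction.

Both reduce to solving, for r, the equation

    r(v) + P(v + r(v)) = phi(v)

(with phi = 0 this is the displacement inverse of P).  For smooth fields
with sub-unit displacement gradients the Picard iteration converges
geometrically.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from patchreg.deform import DisplacementField

__all__ = ["solve_residual", "invert_field"]


def _sample_field_at(field_vectors: np.ndarray, coords: np.ndarray) -> np.ndarray:
    out = np.empty(coords.shape[1:] + (3,), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            field_vectors[..., c].astype(np.float64), coords, order=1, mode="nearest"
        )
    return out


def solve_residual(phi: DisplacementField, P: DisplacementField,
                   n_iter: int = 30, tol: float = 1e-4) -> DisplacementField:
    """Solve r + P o (id + r) = phi for the residual field r.

    Warping by P then by r is then equivalent (to interpolation accuracy)
    to warping by phi once.
    """
    if phi.shape != P.shape:
        raise ValueError("fields must share a lattice")
    shape = phi.shape
    grid = np.indices(shape, dtype=np.float64)
    r = (phi.vectors.astype(np.float64) - P.vectors.astype(np.float64)).copy()
    for _ in range(n_iter):
        coords = np.empty((3,) + shape, dtype=np.float64)
        coords[0] = grid[0] + r[..., 2]
        coords[1] = grid[1] + r[..., 1]
        coords[2] = grid[2] + r[..., 0]
        r_new = phi.vectors.astype(np.float64) - _sample_field_at(P.vectors, coords)
        delta = np.abs(r_new - r).max()
        r = r_new
        if delta < tol:
            break
    return DisplacementField(vectors=r, spacing=phi.spacing)


def invert_field(field: DisplacementField, n_iter: int = 30, tol: float = 1e-4) -> DisplacementField:
    """Displacement inverse g with g(v) + field(v + g(v)) = 0."""
    zero = DisplacementField(
        vectors=np.zeros(field.vectors.shape, dtype=np.float64), spacing=field.spacing
    )
    return solve_residual(zero, field, n_iter=n_iter, tol=tol)
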