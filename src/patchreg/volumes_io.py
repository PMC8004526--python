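"""I/O and intensity normalization for 3D volumes, labels, and fields.

Canonical on-disk format is NIfTI (``.nii`` / ``.nii.gz``): intensity and
label volumes are stored 3D with the in-memory ``(z, y, x)`` axis order
mapped directly to the file's three spatial axes; displacement fields are
stored 4D with shape ``(Z, Y, X, 3)``, vector components ordered
``(ux, uy, uz)`` in voxel units.  Multi-page TIFF stacks (page -> z slice)
are supported read-only for intensity volumes.

Files that carry no usable spacing metadata default to 25 um isotropic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import tifffile

DEFAULT_SPACING_UM = 25.0

__all__ = [
    "Volume3D",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "histogram_match",
    "downsample_isotropic",
]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with per-axis voxel spacing in um.

    ``data`` is indexed ``(z, y, x)``; ``spacing`` is ``(sz, sy, sx)``.
    """

    data: np.ndarray
    spacing: tuple = (DEFAULT_SPACING_UM,) * 3

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D non-negative integer region-ID grid; 0 is background."""

    labels: np.ndarray
    spacing: tuple = (DEFAULT_SPACING_UM,) * 3

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelVolume requires 3D data, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integer-valued")
            self.labels = as_int
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.labels.shape


def _spacing_from_header(img) -> tuple:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    # nibabel reports 1.0 zooms when the writer never set them; treat the
    # all-ones default as "no metadata" and fall back to 25 um.
    if all(abs(z - 1.0) < 1e-9 for z in zooms):
        return (DEFAULT_SPACING_UM,) * 3
    return zooms


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _is_nifti(path: str) -> bool:
    return path.endswith((".nii", ".nii.gz"))


def read_volume(path: str, format: str | None = None) -> Volume3D:
    """Read an intensity volume from NIfTI or a multi-page TIFF stack.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    non-3D payloads.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "nifti" if _is_nifti(path) else "tiff_stack"
    if format == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        return Volume3D(data=data, spacing=_spacing_from_header(img))
    if format == "tiff_stack":
        data = np.asarray(tifffile.imread(path))
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
        return Volume3D(data=data, spacing=(DEFAULT_SPACING_UM,) * 3)
    raise ValueError(f"unknown format {format!r}")


def write_volume(vol: Volume3D, path: str) -> None:
    """Write an intensity volume as NIfTI, preserving spacing metadata."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def read_labels(path: str) -> LabelVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={data.ndim}")
    return LabelVolume(labels=np.rint(data).astype(np.int32), spacing=_spacing_from_header(img))


def write_labels(lab: LabelVolume, path: str) -> None:
    img = nib.Nifti1Image(lab.labels.astype(np.int32), _affine(lab.spacing))
    img.header.set_zooms(lab.spacing)
    nib.save(img, path)


def read_field(path: str):
    """Read a displacement field from a 4D NIfTI of shape (Z, Y, X, 3)."""
    from patchreg.deform import DisplacementField

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected shape (Z, Y, X, 3), got {data.shape}")
    return DisplacementField(vectors=data.astype(np.float32), spacing=_spacing_from_header(img))


def write_field(field, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float32), _affine(field.spacing))
    img.header.set_zooms(tuple(field.spacing) + (1.0,))
    img.header["descrip"] = b"displacement (ux,uy,uz) voxels, axes (z,y,x)"
    nib.save(img, path)


def histogram_match(moving: Volume3D, fixed: Volume3D, n_bins: int = 256) -> Volume3D:
    """Monotone intensity remap of ``moving`` onto ``fixed``'s histogram.

    Empirical-CDF lookup over ``n_bins`` quantiles followed by a linear
    rescale of the result into [0, 1].  Constant-intensity inputs are
    degenerate and rejected.
    """
    mdat = np.asarray(moving.data, dtype=np.float64)
    fdat = np.asarray(fixed.data, dtype=np.float64)
    if mdat.max() == mdat.min() or fdat.max() == fdat.min():
        raise ValueError("histogram matching requires non-constant volumes")
    quantiles = np.linspace(0.0, 1.0, int(n_bins))
    src = np.quantile(mdat, quantiles)
    dst = np.quantile(fdat, quantiles)
    out = np.interp(mdat, src, dst)
    lo, hi = out.min(), out.max()
    out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return Volume3D(data=out, spacing=moving.spacing)


def downsample_isotropic(vol: Volume3D, target_spacing: float) -> Volume3D:
    """Resample to isotropic ``target_spacing`` by trilinear interpolation.

    Output shape per axis is ``round(L * spacing / target_spacing)``.
    Upsampling requests (target below the current maximum spacing) are
    rejected.
    """
    from scipy import ndimage

    target = float(target_spacing)
    if target < max(vol.spacing) - 1e-9:
        raise ValueError(
            f"target spacing {target} um would upsample axes with spacing {vol.spacing}"
        )
    zoom = tuple(s / target for s in vol.spacing)
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return Volume3D(data=vol.data.copy(), spacing=(target,) * 3)
    out = ndimage.zoom(np.asarray(vol.data, dtype=np.float64), zoom, order=1, mode="nearest")
    return Volume3D(data=out, spacing=(target,) * 3)
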