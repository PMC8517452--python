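"""Volumes, masks, and case bundles in standard neuroimaging formats.

The pipeline operates on co-registered axial mpMRI stacks: a T2-weighted
image, an ADC map (10^-6 mm^2/s), a DCE-derived maximum-uptake map (percent
signal increase in the first minute), and a voxel-wise malignancy
probability map, plus an optional binary lesion mask. All channels must
live on the same axis-aligned grid; registration is assumed to have been
done upstream, so volumes whose affine is not diagonal (up to sign) are
rejected rather than silently reoriented.

Arrays are indexed ``data[x, y, z]`` with ``z`` the axial slice index;
``spacing`` is ``(sx, sy, sz)`` in mm and ``origin`` the physical position
of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .exceptions import GeometryError, ImageIOError

#: Geometric agreement tolerance between channels, in mm.
GEOMETRY_TOL_MM = 1e-3


@dataclass
class Volume3D:
    """A scalar 3D image with anisotropic voxel spacing and origin metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ImageIOError(
                f"expected 3D volume, got {self.data.ndim}D array of shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ImageIOError(f"degenerate grid shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ImageIOError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass
class Mask3D:
    """Binary ROI mask aligned to a Volume3D grid. Values are {0, 1}."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ImageIOError(f"expected 3D mask, got {data.ndim}D array")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ImageIOError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ImageIOError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def copy(self) -> "Mask3D":
        return replace(self, data=self.data.copy())


@dataclass
class CaseBundle:
    """The four co-registered mpMRI channels of one case plus optional mask."""

    t2w: Volume3D
    adc: Volume3D
    uptake: Volume3D
    prob: Volume3D
    mask: Mask3D | None = None

    def channels(self) -> dict[str, Volume3D | Mask3D]:
        out: dict[str, Volume3D | Mask3D] = {
            "t2w": self.t2w,
            "adc": self.adc,
            "uptake": self.uptake,
            "prob": self.prob,
        }
        if self.mask is not None:
            out["mask"] = self.mask
        return out


def _affine_to_geometry(affine: np.ndarray, path: str) -> tuple[tuple, tuple]:
    """Extract (spacing, origin) from an axis-aligned NIfTI affine.

    Affines with off-diagonal rotation/shear terms are rejected: the
    pipeline assumes pre-registered axial stacks and never reorients.
    Sign flips on the diagonal (e.g. the common RAS negations) are folded
    into positive spacings.
    """
    lin = affine[:3, :3]
    diag = np.diag(lin)
    off = lin - np.diag(diag)
    if np.max(np.abs(off)) > GEOMETRY_TOL_MM:
        raise ImageIOError(
            f"{path}: non-axis-aligned orientation (direction cosines with "
            "off-diagonal terms); reorient/register upstream"
        )
    spacing = tuple(float(abs(d)) for d in diag)
    origin = tuple(float(t) for t in affine[:3, 3])
    return spacing, origin


def _geometry_to_affine(spacing, origin) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def load_volume(path: str | os.PathLike) -> Volume3D:
    """Load a 3D scalar image (NIfTI-1) with its spacing and origin.

    No resampling or reorientation is performed.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageIOError(f"file not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header error types
        raise ImageIOError(f"{path}: unreadable image ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ImageIOError(f"{path}: expected 3D volume, got {data.ndim}D")
    spacing, origin = _affine_to_geometry(np.asarray(img.affine, dtype=float), path)
    return Volume3D(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def save_volume(vol: Volume3D, path: str | os.PathLike, dtype=np.float32) -> None:
    """Write a Volume3D as NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=dtype), _geometry_to_affine(vol.spacing, vol.origin)
    )
    nib.save(img, os.fspath(path))


def load_mask(path: str | os.PathLike) -> Mask3D:
    """Load a binary mask; any nonzero voxel is treated as foreground."""
    vol = load_volume(path)
    return Mask3D(data=(vol.data > 0.5).astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def save_mask(mask: Mask3D, path: str | os.PathLike) -> None:
    """Write a Mask3D as an unsigned 8-bit NIfTI-1 file."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _geometry_to_affine(mask.spacing, mask.origin)
    )
    nib.save(img, os.fspath(path))


def validate_bundle(bundle: CaseBundle, tol_mm: float = GEOMETRY_TOL_MM) -> CaseBundle:
    """Check that all channels share grid dimensions, spacing, and origin.

    Returns the bundle unchanged if the geometry matches; raises
    :class:`GeometryError` naming the first offending channel otherwise.
    Idempotent and side-effect free.
    """
    ref_name = "t2w"
    ref = bundle.t2w
    for name, ch in bundle.channels().items():
        if ch.shape != ref.shape:
            raise GeometryError(
                f"channel '{name}' grid {ch.shape} does not match '{ref_name}' {ref.shape}"
            )
        for label, a, b in (("spacing", ch.spacing, ref.spacing), ("origin", ch.origin, ref.origin)):
            if max(abs(x - y) for x, y in zip(a, b)) > tol_mm:
                raise GeometryError(
                    f"channel '{name}' {label} {a} differs from '{ref_name}' {b} "
                    f"beyond {tol_mm} mm"
                )
    return bundle
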