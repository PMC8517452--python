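"""Image-processing chain applied to each lesion before feature extraction.

The chain runs in a fixed order: Gaussian de-noising (sigma given in mm and
converted per axis to voxel units), isotropic resampling (trilinear for
images, nearest neighbour for masks), ROI re-segmentation between intensity
percentiles to strip outliers, and fixed-bin-number (FBN) discretization
over the in-mask intensity range. FBN discretization makes texture features
invariant to positive affine rescalings of the intensities, which matters
for non-quantitative T2w signal.

Two bin counts coexist on purpose: a 64-bin discretization feeds the
intensity-histogram statistics, while an independent 32-bin discretization
feeds the GLCM/GLRLM texture matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateDataError
from .imaging_io import Mask3D, Volume3D


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain.

    sigma_mm
        Physical standard deviation of the de-noising Gaussian (mm).
    iso_spacing_mm
        Target isotropic voxel spacing after resampling (mm).
    reseg_lo_pct, reseg_hi_pct
        Percentile window of the in-ROI intensity distribution retained by
        re-segmentation (linear-interpolation percentile convention).
    n_bins_intensity
        Bin count for the intensity-histogram discretization.
    n_bins_texture
        Bin count for the GLCM/GLRLM discretization.
    denoise_t2w, denoise_adc
        Whether de-noising applies to each channel.
    volume_on_resampled
        Measure ROI volume on the resampled mask (before re-segmentation)
        rather than on the native-grid mask.
    """

    sigma_mm: float = 0.5
    iso_spacing_mm: float = 0.5
    reseg_lo_pct: float = 1.0
    reseg_hi_pct: float = 99.0
    n_bins_intensity: int = 64
    n_bins_texture: int = 32
    denoise_t2w: bool = True
    denoise_adc: bool = True
    volume_on_resampled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.reseg_lo_pct < self.reseg_hi_pct <= 100.0):
            raise ValueError(
                f"invalid re-segmentation percentiles ({self.reseg_lo_pct}, {self.reseg_hi_pct})"
            )
        if self.n_bins_intensity < 2 or self.n_bins_texture < 2:
            raise ValueError("bin counts must be >= 2")
        if self.sigma_mm < 0:
            raise ValueError("sigma_mm must be >= 0")
        if self.iso_spacing_mm <= 0:
            raise ValueError("iso_spacing_mm must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


@dataclass
class DiscretizedROI:
    """Integer gray levels over a mask: 1..n_bins inside, 0 outside."""

    levels: np.ndarray
    n_bins: int
    mask: Mask3D

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        inside = self.levels[self.mask.as_bool()]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ValueError("in-mask levels must lie in [1, n_bins]")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.mask.spacing


def denoise_gaussian(vol: Volume3D, sigma_mm: float) -> Volume3D:
    """Isotropic Gaussian smoothing with physical sigma.

    The physical sigma is converted per axis to voxel units by dividing by
    the voxel spacing; boundary handling is reflective. ``sigma_mm = 0``
    returns the input unchanged.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return vol
    sigma_vox = [sigma_mm / s for s in vol.spacing]
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float64), sigma=sigma_vox, mode="reflect"
    )
    return Volume3D(data=out, spacing=vol.spacing, origin=vol.origin)


def _resample_grid(shape, spacing, target_mm):
    """Output shape and per-axis sample coordinates for corner-aligned resampling.

    The position of voxel 0 is preserved and the output grid is the densest
    grid at the target spacing that stays inside the input sample range, so
    interpolation never extrapolates. Physical extent (center-to-center) is
    preserved within one voxel.
    """
    out_shape = []
    coords_1d = []
    for n, s in zip(shape, spacing):
        n_out = int(np.floor((n - 1) * s / target_mm + 1e-9)) + 1
        n_out = max(n_out, 1)
        c = np.arange(n_out) * (target_mm / s)
        c = np.clip(c, 0, n - 1)
        out_shape.append(n_out)
        coords_1d.append(c)
    return tuple(out_shape), coords_1d


def resample_isotropic(
    vol: Volume3D | Mask3D, target_mm: float, method: str | None = None
) -> Volume3D | Mask3D:
    """Resample to isotropic spacing: trilinear for images, nearest for masks.

    Masks are always resampled nearest-neighbour so outputs stay binary.
    A volume already at the target spacing is returned unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    is_mask = isinstance(vol, Mask3D)
    if method is None:
        method = "nearest" if is_mask else "trilinear"
    if is_mask and method != "nearest":
        method = "nearest"
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation method '{method}'")
    if all(abs(s - target_mm) < 1e-9 for s in vol.spacing):
        return vol

    out_shape, coords_1d = _resample_grid(vol.shape, vol.spacing, target_mm)
    grid = np.meshgrid(*coords_1d, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    order = 1 if method == "trilinear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64), coords, order=order, mode="nearest"
    ).reshape(out_shape)
    spacing = (target_mm,) * 3
    if is_mask:
        return Mask3D(data=(out > 0.5).astype(np.uint8), spacing=spacing, origin=vol.origin)
    return Volume3D(data=out, spacing=spacing, origin=vol.origin)


def resegment_roi(vol: Volume3D, mask: Mask3D, lo_pct: float, hi_pct: float) -> Mask3D:
    """Keep only mask voxels whose intensity lies within the in-ROI
    [P_lo, P_hi] percentile window (inclusive).

    Percentiles use the linear-interpolation convention between order
    statistics. Idempotent: re-applying with the same window is a no-op.
    """
    if not (0.0 <= lo_pct < hi_pct <= 100.0):
        raise ValueError(f"invalid percentile window ({lo_pct}, {hi_pct})")
    inside = mask.as_bool()
    if not inside.any():
        raise DegenerateDataError("re-segmentation received an empty mask")
    vals = vol.data[inside]
    p_lo, p_hi = np.percentile(vals, [lo_pct, hi_pct])
    keep = inside & (vol.data >= p_lo) & (vol.data <= p_hi)
    if not keep.any():
        raise DegenerateDataError("re-segmentation removed all voxels")
    return Mask3D(data=keep.astype(np.uint8), spacing=mask.spacing, origin=mask.origin)


def discretize_fbn(vol: Volume3D, mask: Mask3D, n_bins: int) -> DiscretizedROI:
    """Fixed-bin-number discretization over the in-mask intensity range.

    level(v) = min(n_bins, 1 + floor(n_bins * (x_v - x_min) / (x_max - x_min)));
    a constant ROI maps every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    inside = mask.as_bool()
    if not inside.any():
        raise DegenerateDataError("discretization received an empty mask")
    vals = vol.data[inside]
    x_min, x_max = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if x_max == x_min:
        levels[inside] = 1
    else:
        lv = 1 + np.floor(n_bins * (vals - x_min) / (x_max - x_min))
        levels[inside] = np.minimum(lv, n_bins).astype(np.int32)
    return DiscretizedROI(levels=levels, n_bins=n_bins, mask=mask)
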