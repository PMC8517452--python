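"""Rule-based lesion-candidate detection from co-registered mpMRI maps.

A voxel survives iff its malignancy probability, ADC value, and first-minute
maximum contrast uptake all fall on the keep side of their thresholds
(discards are phrased strictly, so keeps are inclusive). Surviving voxels
are grouped into 26-connected 3D components; a component becomes a
candidate only if its area strictly exceeds the threshold (100 mm^2 by
default). "Area" of a 3D component defaults to the volume-equivalent
reading — component volume divided by the axial slice thickness — under
which the 100 mm^2 threshold equals 60% of the smallest clinically
significant lesion volume (0.5 ml) on 3 mm slices; the maximal axial
cross-section is available as an alternative.

The human step of picking the true lesion among candidates is replaced by
an overlap surrogate: the candidate with maximal Dice against a reference
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imaging_io import CaseBundle, Mask3D, validate_bundle


@dataclass
class DetectionConfig:
    """Voxel- and region-level detection thresholds.

    ADC bounds are expressed in 10^-6 mm^2/s (the standard prostate ADC
    scale), recorded explicitly in ``adc_units``.
    """

    prob_min: float = 0.60
    adc_min: float = 200.0
    adc_max: float = 1600.0
    uptake_min: float = 100.0
    min_area_mm2: float = 100.0
    adc_units: str = "1e-6 mm^2/s"
    connectivity: int = 26  # 6, 18 or 26
    # "volume_equivalent": area = component volume / axial slice thickness,
    # the reading under which 100 mm^2 is 60% of the smallest clinically
    # significant lesion (0.5 ml) on 3 mm slices and under which every
    # >=0.5 ml lesion passes. "max_axial": largest per-slice cross-section.
    area_mode: str = "volume_equivalent"

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_min <= 1.0):
            raise ValueError("prob_min must be in [0, 1]")
        if self.adc_min >= self.adc_max:
            raise ValueError("adc_min must be < adc_max")
        if self.min_area_mm2 <= 0:
            raise ValueError("min_area_mm2 must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        return cls(**d)


@dataclass
class CandidateRegion:
    """A connected suspicious region."""

    voxel_indices: np.ndarray  # (n, 3) int grid indices
    volume_mm3: float
    max_axial_area_mm2: float
    centroid_mm: tuple[float, float, float]
    label: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def to_mask(self, like: Mask3D) -> Mask3D:
        data = np.zeros(like.shape, dtype=np.uint8)
        data[tuple(self.voxel_indices.T)] = 1
        return Mask3D(data=data, spacing=like.spacing, origin=like.origin)


def filter_voxels(bundle: CaseBundle, cfg: DetectionConfig | None = None) -> Mask3D:
    """Keep voxels passing all three rules (inclusive on the keep side):
    prob >= prob_min, adc_min <= adc <= adc_max, uptake >= uptake_min.

    Monotone: relaxing any threshold never removes a kept voxel.
    """
    cfg = cfg or DetectionConfig()
    validate_bundle(bundle)
    keep = (
        (bundle.prob.data >= cfg.prob_min)
        & (bundle.adc.data >= cfg.adc_min)
        & (bundle.adc.data <= cfg.adc_max)
        & (bundle.uptake.data >= cfg.uptake_min)
    )
    return Mask3D(data=keep.astype(np.uint8), spacing=bundle.prob.spacing, origin=bundle.prob.origin)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def extract_candidates(kept: Mask3D, cfg: DetectionConfig | None = None) -> list[CandidateRegion]:
    """Label connected components and emit those whose maximum axial
    cross-sectional area strictly exceeds ``min_area_mm2``, sorted by
    descending volume. An empty kept mask yields an empty list."""
    cfg = cfg or DetectionConfig()
    sx, sy, sz = kept.spacing
    pixel_area = sx * sy
    voxel_volume = kept.voxel_volume_mm3
    labels, n_comp = ndimage.label(kept.as_bool(), structure=_connectivity_structure(cfg.connectivity))
    candidates: list[CandidateRegion] = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labels == lab)
        n = idx.shape[0]
        volume = n * voxel_volume
        # largest per-slice (axial, fixed z) cross-section
        z_counts = np.bincount(idx[:, 2])
        max_area = float(z_counts.max()) * pixel_area
        area = volume / sz if cfg.area_mode == "volume_equivalent" else max_area
        if area > cfg.min_area_mm2:
            centroid = tuple(
                float(o + c * s)
                for o, c, s in zip(kept.origin, idx.mean(axis=0), kept.spacing)
            )
            candidates.append(
                CandidateRegion(
                    voxel_indices=idx,
                    volume_mm3=float(volume),
                    max_axial_area_mm2=float(max_area),
                    centroid_mm=centroid,
                    label=lab,
                )
            )
    candidates.sort(key=lambda c: -c.volume_mm3)
    for i, c in enumerate(candidates, start=1):
        c.label = i
    return candidates


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean arrays."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float((a & b).sum()) / float(denom)


def select_lesion(
    candidates: list[CandidateRegion], reference: Mask3D
) -> CandidateRegion | None:
    """Automated surrogate for radiologist lesion confirmation: return the
    candidate with maximal Dice overlap against the reference mask, or
    ``None`` if there are no candidates."""
    if reference.n_voxels == 0:
        raise ValueError("reference mask is empty")
    if not candidates:
        return None
    ref = reference.as_bool()
    best, best_dice = None, -1.0
    for cand in candidates:
        mask = np.zeros(reference.shape, dtype=bool)
        mask[tuple(cand.voxel_indices.T)] = True
        d = dice_coefficient(mask, ref)
        if d > best_dice:
            best, best_dice = cand, d
    return best


def candidates_to_labelmap(candidates: list[CandidateRegion], like: Mask3D) -> np.ndarray:
    """Labeled integer volume (candidate ids) for export."""
    out = np.zeros(like.shape, dtype=np.int16)
    for cand in candidates:
        out[tuple(cand.voxel_indices.T)] = cand.label
    return out
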