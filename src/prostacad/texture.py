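"""IBSI-style 3D radiomics: the 92-feature lesion vector.

Per lesion the vector contains: ROI volume (1); intensity statistics of the
raw in-mask ADC values plus intensity-histogram statistics on 64-bin
discretized levels (9); 25 gray-level co-occurrence (GLCM) features and 16
gray-level run-length (GLRLM) features from each of the ADC map and the T2w
image (82). T2w contributes texture only — its signal is non-quantitative,
so intensity statistics are restricted to ADC.

Texture matrices are computed at one-voxel distance for each of the 13
unique non-antiparallel directions of the 26-neighbourhood and the features
are arithmetically averaged over directions, which makes them invariant
under the axis-aligned symmetries of the cube once the grid is isotropic.
GLCMs are symmetrized and normalized per direction; GLRLM runs are maximal
in-mask runs (a masked-out voxel terminates a run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError
from .imaging_io import CaseBundle, Mask3D, Volume3D, validate_bundle
from .preprocess import (
    DiscretizedROI,
    PreprocessConfig,
    denoise_gaussian,
    discretize_fbn,
    resample_isotropic,
    resegment_roi,
)

# --------------------------------------------------------------------------
# Canonical feature naming (frozen public contract)

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
)

INTENSITY_STAT_NAMES: tuple[str, ...] = (
    "mean",
    "p25",
    "p50",
    "p75",
    "skewness",
    "kurtosis",
    "intensity_kurtosis",
    "intensity_variance",
    "intensity_hist_mean",
)

FEATURE_NAMES: tuple[str, ...] = (
    ("roi_volume_mm3",)
    + tuple(f"adc_{n}" for n in INTENSITY_STAT_NAMES)
    + tuple(f"adc_glcm_{n}" for n in GLCM_FEATURE_NAMES)
    + tuple(f"t2w_glcm_{n}" for n in GLCM_FEATURE_NAMES)
    + tuple(f"adc_glrlm_{n}" for n in GLRLM_FEATURE_NAMES)
    + tuple(f"t2w_glrlm_{n}" for n in GLRLM_FEATURE_NAMES)
)
assert len(FEATURE_NAMES) == 92


@dataclass
class FeatureVector:
    """The named 92-component radiomics vector for one lesion."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry the canonical 92 names in order; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=list(FEATURE_NAMES), dtype=float)


@dataclass
class TextureMatrix:
    """One direction's co-occurrence or run-length matrix."""

    kind: str  # "GLCM" | "GLRLM"
    matrix: np.ndarray
    direction: tuple[int, int, int]
    n_bins: int
    n_observations: int  # voxel pairs (GLCM) or in-mask voxels (GLRLM)

    @property
    def empty(self) -> bool:
        return self.n_observations == 0 or self.matrix.sum() == 0


# --------------------------------------------------------------------------
# Directions

def direction_offsets_3d() -> list[tuple[int, int, int]]:
    """The 13 unique non-antiparallel offsets of the 26-neighbourhood.

    Canonical order: lexicographic over (dx, dy, dz), keeping the member of
    each antiparallel pair whose first nonzero component is positive.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                o = (dx, dy, dz)
                if o == (0, 0, 0):
                    continue
                first = next(c for c in o if c != 0)
                if first > 0:
                    offsets.append(o)
    return offsets


def _shifted_slices(shape, offset):
    """Index slices (a, b) such that arr[a] and arr[b] are voxel pairs
    separated by ``offset`` (b = a + offset). Empty slices if the offset
    exceeds the grid."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl_a.append(slice(0, max(n - d, 0)))
            sl_b.append(slice(min(d, n), n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, max(n + d, 0)))
    return tuple(sl_a), tuple(sl_b)


# --------------------------------------------------------------------------
# GLCM

def glcm_matrix(roi: DiscretizedROI, offset: tuple[int, int, int], distance: int = 1) -> TextureMatrix:
    """Symmetrized, normalized co-occurrence matrix for one direction.

    Counts level pairs of in-mask voxels separated by ``offset * distance``
    (both endpoints in the mask), adds the transpose, and normalizes to
    sum 1. A direction with no valid pair yields an all-zero matrix with
    ``n_observations = 0`` and is excluded from direction averages.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    nb = roi.n_bins
    step = tuple(int(o) * distance for o in offset)
    sl_a, sl_b = _shifted_slices(roi.levels.shape, step)
    a = roi.levels[sl_a].ravel()
    b = roi.levels[sl_b].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid], b[valid]
    counts = np.bincount((a - 1) * nb + (b - 1), minlength=nb * nb).reshape(nb, nb).astype(float)
    counts = counts + counts.T  # symmetrize: each pair counted in both orders
    total = counts.sum()
    matrix = counts / total if total > 0 else counts
    return TextureMatrix(
        kind="GLCM", matrix=matrix, direction=tuple(offset), n_bins=nb, n_observations=int(a.size)
    )


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The 25 GLCM features of a single normalized symmetric matrix."""
    nb = P.shape[0]
    lv = np.arange(1, nb + 1, dtype=float)
    I = lv[:, None] * np.ones((1, nb))
    J = I.T
    px = P.sum(axis=1)  # row marginal (= column marginal by symmetry)
    mu = float((lv * px).sum())
    var = float((((lv - mu) ** 2) * px).sum())

    absdiff = np.abs(I - J).astype(int)
    d_k = np.bincount(absdiff.ravel(), weights=P.ravel(), minlength=nb)  # k = 0..nb-1
    ks = np.arange(nb, dtype=float)
    diff_avg = float((ks * d_k).sum())

    sums = (I + J).astype(int)
    s_k = np.bincount(sums.ravel(), weights=P.ravel(), minlength=2 * nb + 1)  # k = 0..2nb
    ms = np.arange(2 * nb + 1, dtype=float)
    sum_avg = float((ms * s_k).sum())

    joint_entropy = _entropy2(P.ravel())
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum()) if nz.any() else 0.0
    hxy2 = _entropy2(pxpy.ravel())

    if hx > 0:
        ic1 = (joint_entropy - hxy1) / hx
        ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))
    else:
        ic1 = 0.0
        ic2 = 0.0

    offdiag = absdiff > 0
    inv_var = float((P[offdiag] / (I - J)[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    autocorr = float((I * J * P).sum())

    feats = {
        "joint_maximum": float(P.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": joint_entropy,
        "difference_average": diff_avg,
        "difference_variance": float((((ks - diff_avg) ** 2) * d_k).sum()),
        "difference_entropy": _entropy2(d_k),
        "sum_average": sum_avg,
        "sum_variance": float((((ms - sum_avg) ** 2) * s_k).sum()),
        "sum_entropy": _entropy2(s_k),
        "angular_second_moment": float((P**2).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "dissimilarity": float((np.abs(I - J) * P).sum()),
        "inverse_difference": float((P / (1.0 + np.abs(I - J))).sum()),
        "inverse_difference_normalized": float((P / (1.0 + np.abs(I - J) / nb)).sum()),
        "inverse_difference_moment": float((P / (1.0 + (I - J) ** 2)).sum()),
        "inverse_difference_moment_normalized": float((P / (1.0 + (I - J) ** 2 / nb**2)).sum()),
        "inverse_variance": inv_var,
        # zero-variance (single-level) matrix: perfectly correlated by convention
        "correlation": (autocorr - mu * mu) / var if var > 0 else 1.0,
        "autocorrelation": autocorr,
        "cluster_tendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "cluster_shade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "cluster_prominence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "information_correlation_1": ic1,
        "information_correlation_2": ic2,
    }
    return feats


def glcm_features(roi: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """25 GLCM features, each averaged over the 13 directions.

    Directions with no valid voxel pair are excluded from the average.
    """
    per_dir = []
    for off in direction_offsets_3d():
        tm = glcm_matrix(roi, off, distance=distance)
        if not tm.empty:
            per_dir.append(glcm_features_from_matrix(tm.matrix))
    if not per_dir:
        raise DegenerateDataError("no direction produced a co-occurrence pair")
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURE_NAMES
    }


# --------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(roi: DiscretizedROI, offset: tuple[int, int, int]) -> TextureMatrix:
    """Run-length counts for one direction.

    Entry (i, j) counts maximal runs of gray level i+1 with length j+1
    along ``offset``; a masked-out voxel terminates a run. The counts per
    direction sum to the number of maximal runs, and the length-weighted
    sum equals the number of in-mask voxels.
    """
    levels = roi.levels
    inside = levels > 0
    n_vox = int(inside.sum())
    nb = roi.n_bins
    if n_vox == 0:
        return TextureMatrix("GLRLM", np.zeros((nb, 1)), tuple(offset), nb, 0)

    # same[v] <=> v and v+offset are both in-mask with equal level
    sl_a, sl_b = _shifted_slices(levels.shape, offset)
    same = np.zeros(levels.shape, dtype=bool)
    same[sl_a] = inside[sl_a] & inside[sl_b] & (levels[sl_a] == levels[sl_b])

    # run length from each voxel toward +offset:
    # L[v] = 1 + L[v + offset] if same[v] else (1 if in-mask)
    # processed plane-by-plane along the first axis the offset moves in,
    # so L[v + offset] is always already available.
    axis = next(k for k, d in enumerate(offset) if d != 0)
    d = offset[axis]
    other = [k for k in range(3) if k != axis]
    roll_shift = tuple(-offset[k] for k in other)
    n_ax = levels.shape[axis]
    L = np.zeros(levels.shape, dtype=np.int32)

    def take(arr, i):
        sl = [slice(None)] * 3
        sl[axis] = i
        return arr[tuple(sl)]

    order = range(n_ax - 1, -1, -1) if d > 0 else range(n_ax)
    for i in order:
        j = i + d
        cur = np.where(take(inside, i), 1, 0).astype(np.int32)
        if 0 <= j < n_ax:
            nbr = np.roll(take(L, j), roll_shift, axis=(0, 1))
            cur = np.where(take(same, i), 1 + nbr, cur)
        sl = [slice(None)] * 3
        sl[axis] = i
        L[tuple(sl)] = cur

    # run starts: in-mask voxels with no continuing predecessor at v-offset
    cont = np.zeros(levels.shape, dtype=bool)
    cont[sl_b] = same[sl_a]
    starts = inside & ~cont
    run_levels = levels[starts]
    run_lengths = L[starts]
    max_len = int(run_lengths.max())
    R = np.zeros((nb, max_len), dtype=float)
    np.add.at(R, (run_levels - 1, run_lengths - 1), 1.0)
    return TextureMatrix("GLRLM", R, tuple(offset), nb, n_vox)


def glrlm_features_from_matrix(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLRLM features of one direction's run-count matrix."""
    ns = R.sum()
    if ns == 0:
        raise DegenerateDataError("empty run-length matrix")
    nb, max_len = R.shape
    i = np.arange(1, nb + 1, dtype=float)[:, None]
    j = np.arange(1, max_len + 1, dtype=float)[None, :]
    r_i = R.sum(axis=1)  # runs per gray level
    r_j = R.sum(axis=0)  # runs per length
    p = R / ns
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return {
        "short_run_emphasis": float((R / j**2).sum() / ns),
        "long_run_emphasis": float((R * j**2).sum() / ns),
        "low_gray_level_run_emphasis": float((R / i**2).sum() / ns),
        "high_gray_level_run_emphasis": float((R * i**2).sum() / ns),
        "short_run_low_gray_level_emphasis": float((R / (i**2 * j**2)).sum() / ns),
        "short_run_high_gray_level_emphasis": float((R * i**2 / j**2).sum() / ns),
        "long_run_low_gray_level_emphasis": float((R * j**2 / i**2).sum() / ns),
        "long_run_high_gray_level_emphasis": float((R * i**2 * j**2).sum() / ns),
        "gray_level_non_uniformity": float((r_i**2).sum() / ns),
        "gray_level_non_uniformity_normalized": float((r_i**2).sum() / ns**2),
        "run_length_non_uniformity": float((r_j**2).sum() / ns),
        "run_length_non_uniformity_normalized": float((r_j**2).sum() / ns**2),
        "run_percentage": float(ns / n_voxels),
        "gray_level_variance": float((((i - mu_i) ** 2) * p).sum()),
        "run_length_variance": float((((j - mu_j) ** 2) * p).sum()),
        "run_entropy": _entropy2(p.ravel()),
    }


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 GLRLM features averaged over the 13 directions."""
    per_dir = []
    for off in direction_offsets_3d():
        tm = glrlm_matrix(roi, off)
        if not tm.empty:
            per_dir.append(glrlm_features_from_matrix(tm.matrix, tm.n_observations))
    if not per_dir:
        raise DegenerateDataError("no direction produced any run")
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURE_NAMES
    }


# --------------------------------------------------------------------------
# Intensity statistics and volume

def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    m = float(x.mean())
    c = x - m
    m2 = float((c**2).mean())
    m3 = float((c**3).mean())
    m4 = float((c**4).mean())
    return m, m2, m3, m4


def intensity_statistics(
    adc_vol: Volume3D, mask: Mask3D, n_bins_intensity: int = 64
) -> dict[str, float]:
    """Nine ADC intensity descriptors.

    ``mean/p25/p50/p75/skewness/kurtosis`` are computed on the raw in-mask
    values (Fisher skewness and excess kurtosis, population moments; both
    defined as 0 when the in-mask variance is zero). ``intensity_kurtosis``,
    ``intensity_variance``, and ``intensity_hist_mean`` are the same
    moments taken on the fixed-bin-number discretized levels
    (intensity-histogram statistics).
    """
    inside = mask.as_bool()
    if not inside.any():
        raise DegenerateDataError("intensity statistics on an empty mask")
    vals = adc_vol.data[inside].astype(float)
    m, m2, m3, m4 = _moments(vals)
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0

    levels = discretize_fbn(adc_vol, mask, n_bins_intensity).levels[inside].astype(float)
    hm, h2, _, h4 = _moments(levels)
    h_kurt = h4 / h2**2 - 3.0 if h2 > 0 else 0.0

    p25, p50, p75 = np.percentile(vals, [25, 50, 75])
    return {
        "mean": m,
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "intensity_kurtosis": float(h_kurt),
        "intensity_variance": float(h2),
        "intensity_hist_mean": float(hm),
    }


def roi_volume(mask: Mask3D) -> float:
    """Physical ROI volume: voxel count x voxel volume (mm^3)."""
    n = mask.n_voxels
    if n == 0:
        raise DegenerateDataError("volume of an empty mask")
    return n * mask.voxel_volume_mm3


# --------------------------------------------------------------------------
# Full extraction

def _crop_to_mask(vols: list[Volume3D], mask: Mask3D, margin_vox: int):
    """Crop channels and mask to the mask bounding box plus a margin,
    keeping origins consistent. Speeds up resampling without touching
    in-mask values (the margin covers interpolation support)."""
    idx = np.argwhere(mask.as_bool())
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    origin = tuple(o + int(l) * s for o, l, s in zip(mask.origin, lo, mask.spacing))
    out_vols = [Volume3D(v.data[sl], v.spacing, origin) for v in vols]
    out_mask = Mask3D(mask.data[sl], mask.spacing, origin)
    return out_vols, out_mask


def extract_feature_vector(
    bundle: CaseBundle, mask: Mask3D, cfg: PreprocessConfig | None = None
) -> FeatureVector:
    """Run the full preprocessing chain and assemble the 92-feature vector.

    Chain per channel: Gaussian de-noise -> isotropic resample (trilinear
    image / nearest mask) -> per-channel percentile re-segmentation ->
    FBN discretization (64 bins for intensity-histogram statistics, 32 for
    texture matrices). ADC contributes intensity + texture; T2w texture only.
    """
    cfg = cfg or PreprocessConfig()
    validate_bundle(bundle)
    if mask.n_voxels == 0:
        raise DegenerateDataError("feature extraction on an empty lesion mask")

    adc, t2w = bundle.adc, bundle.t2w
    if cfg.denoise_adc:
        adc = denoise_gaussian(adc, cfg.sigma_mm)
    if cfg.denoise_t2w:
        t2w = denoise_gaussian(t2w, cfg.sigma_mm)

    margin = int(np.ceil(4 * cfg.sigma_mm / min(mask.spacing))) + 4
    (adc, t2w), mask_c = _crop_to_mask([adc, t2w], mask, margin)

    adc_r = resample_isotropic(adc, cfg.iso_spacing_mm, "trilinear")
    t2w_r = resample_isotropic(t2w, cfg.iso_spacing_mm, "trilinear")
    mask_r = resample_isotropic(mask_c, cfg.iso_spacing_mm)
    if mask_r.n_voxels == 0:
        raise DegenerateDataError("lesion mask vanished under isotropic resampling")

    volume = roi_volume(mask_r if cfg.volume_on_resampled else mask)

    values: dict[str, float] = {"roi_volume_mm3": volume}

    mask_adc = resegment_roi(adc_r, mask_r, cfg.reseg_lo_pct, cfg.reseg_hi_pct)
    stats = intensity_statistics(adc_r, mask_adc, cfg.n_bins_intensity)
    for name in INTENSITY_STAT_NAMES:
        values[f"adc_{name}"] = stats[name]

    roi_adc = discretize_fbn(adc_r, mask_adc, cfg.n_bins_texture)
    mask_t2w = resegment_roi(t2w_r, mask_r, cfg.reseg_lo_pct, cfg.reseg_hi_pct)
    roi_t2w = discretize_fbn(t2w_r, mask_t2w, cfg.n_bins_texture)

    for prefix, roi in (("adc", roi_adc), ("t2w", roi_t2w)):
        for name, val in glcm_features(roi).items():
            values[f"{prefix}_glcm_{name}"] = val
    for prefix, roi in (("adc", roi_adc), ("t2w", roi_t2w)):
        for name, val in glrlm_features(roi).items():
            values[f"{prefix}_glrlm_{name}"] = val

    # restore canonical order
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(values=ordered)
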