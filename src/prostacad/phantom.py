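"""Seeded synthetic mpMRI phantoms and feature tables.

The phantom emulates the statistical structure the pipeline assumes rather
than MR physics: an ellipsoidal gland on a quiet background, with planted
ellipsoidal lesions of two generative classes mirroring low (GG <= 2) and
high (GG > 2) aggressive prostate cancer. High-aggressive lesions are
larger on average, have lower ADC (the well-known inverse ADC-grade
relation, here a simulation assumption), and rougher texture — implemented
as a shorter Gaussian-random-field correlation length. Lesion voxels carry
probability-map and uptake plateaus above the detection thresholds so that
planted lesions are recoverable by the candidate rules.

The feature-table generator provides the substrate for the selection and
classification stages: multivariate Gaussian features with a known
informative subset (class mean shift in sd units) and optional
high-correlation blocks to exercise redundancy pruning.

Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import CaseBundle, Mask3D, Volume3D
from .selection import FeatureTable
from .texture import FEATURE_NAMES


@dataclass
class LesionClassSpec:
    """Generative parameters of one aggressiveness class."""

    adc_mean: float  # 1e-6 mm^2/s
    adc_sd: float
    t2w_mean: float  # arbitrary units
    t2w_sd: float
    corr_len_mm: float  # texture correlation length
    volume_range_ml: tuple[float, float]


#: Low-aggressive (GG <= 2): higher ADC, smoother texture, smaller volume.
LOW_AGGRESSIVE = LesionClassSpec(
    adc_mean=1100.0, adc_sd=110.0, t2w_mean=260.0, t2w_sd=35.0,
    corr_len_mm=3.0, volume_range_ml=(0.5, 1.2),
)
#: High-aggressive (GG > 2): lower ADC, rougher texture, larger volume.
HIGH_AGGRESSIVE = LesionClassSpec(
    adc_mean=850.0, adc_sd=130.0, t2w_mean=225.0, t2w_sd=45.0,
    corr_len_mm=1.2, volume_range_ml=(0.8, 2.5),
)


@dataclass
class PhantomSpec:
    """Full description of one synthetic case."""

    grid_shape: tuple[int, int, int] = (80, 80, 24)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 2.4)
    n_lesions: int = 2
    lesion_labels: tuple[int, ...] | None = None  # 1 = high aggressive
    low: LesionClassSpec = field(default_factory=lambda: LOW_AGGRESSIVE)
    high: LesionClassSpec = field(default_factory=lambda: HIGH_AGGRESSIVE)
    background_adc: tuple[float, float] = (1450.0, 90.0)  # mean, sd
    background_t2w: tuple[float, float] = (360.0, 50.0)
    background_corr_len_mm: float = 4.0
    prob_plateau: float = 0.85
    uptake_plateau: float = 150.0
    background_prob: float = 0.08
    background_uptake: float = 40.0
    noise_sd_adc: float = 25.0
    noise_sd_t2w: float = 12.0
    prevalence: float = 0.41  # class mix when lesion_labels is None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high.adc_mean >= self.low.adc_mean:
            raise ValueError(
                "high-aggressive ADC mean must be below low-aggressive "
                "(inverse ADC-grade relation)"
            )
        if min(self.low.volume_range_ml[0], self.high.volume_range_ml[0]) < 0.5:
            raise ValueError("lesion volumes must be >= 0.5 ml")


def _grf(rng: np.random.Generator, shape, spacing, corr_len_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with a physical correlation length."""
    sigma_vox = [corr_len_mm / s for s in spacing]
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="reflect")
    sd = g.std()
    return (g - g.mean()) / sd if sd > 0 else g


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center_mm, semi_axes_mm):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def simulate_phantom(spec: PhantomSpec) -> tuple[CaseBundle, list[Mask3D], list[int]]:
    """Generate one case: four consistent channels, per-lesion truth masks,
    and per-lesion class labels. Deterministic in ``spec`` (incl. seed).

    Lesions are placed inside the gland without overlap; each placement is
    retried up to 100 times before failing.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]
    gland_axes = [0.42 * e for e in extent]
    gland = _ellipsoid_mask(shape, spacing, center, gland_axes)

    if spec.lesion_labels is not None:
        labels = [int(l) for l in spec.lesion_labels]
        if len(labels) != spec.n_lesions:
            raise ValueError("lesion_labels length must equal n_lesions")
    else:
        labels = [int(rng.random() < spec.prevalence) for _ in range(spec.n_lesions)]

    truth_masks: list[np.ndarray] = []
    occupied = np.zeros(shape, dtype=bool)
    for lab in labels:
        cls = spec.high if lab == 1 else spec.low
        placed = False
        for _ in range(100):
            vol_mm3 = rng.uniform(*cls.volume_range_ml) * 1000.0
            r = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
            f = rng.uniform(0.8, 1.25, size=3)
            f /= f.prod() ** (1.0 / 3.0)
            axes = r * f
            lo = [c - (g - a) for c, g, a in zip(center, gland_axes, axes)]
            hi = [c + (g - a) for c, g, a in zip(center, gland_axes, axes)]
            pos = [rng.uniform(l, h) for l, h in zip(lo, hi)]
            lesion = _ellipsoid_mask(shape, spacing, pos, axes)
            margin = ndimage.binary_dilation(lesion, iterations=2)
            if lesion.sum() == 0 or (margin & occupied).any():
                continue
            if (lesion & ~gland).sum() > 0.2 * lesion.sum():
                continue
            truth_masks.append(lesion)
            occupied |= margin
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a non-overlapping lesion in 100 attempts")

    # background fields
    bg = _grf(rng, shape, spacing, spec.background_corr_len_mm)
    adc = spec.background_adc[0] + spec.background_adc[1] * bg
    t2w = spec.background_t2w[0] + spec.background_t2w[1] * _grf(
        rng, shape, spacing, spec.background_corr_len_mm
    )
    prob = np.clip(
        spec.background_prob + 0.05 * _grf(rng, shape, spacing, spec.background_corr_len_mm),
        0.0,
        0.45,
    )
    uptake = spec.background_uptake + 10.0 * _grf(rng, shape, spacing, spec.background_corr_len_mm)

    # one texture field per class correlation length, shared across lesions
    tex = {
        0: _grf(rng, shape, spacing, spec.low.corr_len_mm),
        1: _grf(rng, shape, spacing, spec.high.corr_len_mm),
    }
    for lesion, lab in zip(truth_masks, labels):
        cls = spec.high if lab == 1 else spec.low
        n = int(lesion.sum())
        adc[lesion] = np.clip(
            cls.adc_mean
            + cls.adc_sd * tex[lab][lesion]
            + spec.noise_sd_adc * rng.standard_normal(n),
            300.0,
            1550.0,
        )
        t2w[lesion] = np.clip(
            cls.t2w_mean
            + cls.t2w_sd * tex[lab][lesion]
            + spec.noise_sd_t2w * rng.standard_normal(n),
            10.0,
            None,
        )
        prob[lesion] = np.clip(
            spec.prob_plateau + 0.08 * np.abs(rng.standard_normal(n)), spec.prob_plateau, 0.99
        )
        uptake[lesion] = spec.uptake_plateau + 25.0 * np.abs(rng.standard_normal(n))

    t2w = np.clip(t2w, 1.0, None)
    adc = np.clip(adc, 50.0, None)

    bundle = CaseBundle(
        t2w=Volume3D(t2w, spacing),
        adc=Volume3D(adc, spacing),
        uptake=Volume3D(uptake, spacing),
        prob=Volume3D(np.clip(prob, 0.0, 1.0), spacing),
    )
    masks = [Mask3D(m.astype(np.uint8), spacing) for m in truth_masks]
    return bundle, masks, labels


def simulate_cohort(
    n_cases: int, seed: int = 0, prevalence: float = 0.41, **spec_overrides
) -> list[tuple[str, CaseBundle, Mask3D, int]]:
    """A list of single-lesion cases (case_id, bundle, truth mask, label)
    with the class mix fixed by ``prevalence`` (deterministic count)."""
    n_pos = int(round(n_cases * prevalence))
    labels = [1] * n_pos + [0] * (n_cases - n_pos)
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n_cases)]
    out = []
    for i, lab in enumerate(labels):
        spec = PhantomSpec(
            n_lesions=1, lesion_labels=(lab,), seed=(seed * 100003 + i) % (2**31),
            **spec_overrides,
        )
        bundle, masks, _ = simulate_phantom(spec)
        out.append((f"case_{i:03d}", bundle, masks[0], lab))
    return out


# --------------------------------------------------------------------------
# Feature tables

@dataclass
class TableSpec:
    """Generative description of a synthetic lesion-by-feature table."""

    n_rows: int = 200
    n_features: int = 92
    informative: tuple[int, ...] = (0, 1, 2)
    delta_mu: float = 1.5  # class mean shift in sd units
    correlated_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    prevalence: float = 0.41
    two_lesion_frac: float = 0.12  # fraction of rows paired into one patient
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.informative and self.delta_mu != 0:
            raise ValueError("informative set empty but delta_mu nonzero")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")


def simulate_feature_table(spec: TableSpec) -> FeatureTable:
    """Multivariate Gaussian features with a known informative subset.

    Informative columns are shifted by ``delta_mu`` (in sd units) for the
    positive class; columns inside a correlation block share a latent
    factor giving pairwise correlation rho. Rows are patient-grouped with
    a fraction of two-lesion patients."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_rows, spec.n_features
    n_pos = int(round(n * spec.prevalence))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    labels = labels[rng.permutation(n)]

    Z = rng.standard_normal((n, p))
    for idxs, rho in spec.correlated_blocks:
        shared = rng.standard_normal(n)
        for i in idxs:
            Z[:, i] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(n)
    for i in spec.informative:
        Z[labels == 1, i] += spec.delta_mu

    groups = np.arange(n)
    n_pairs = int(n * spec.two_lesion_frac / 2.0)
    perm = rng.permutation(n)
    for k in range(n_pairs):
        groups[perm[2 * k + 1]] = groups[perm[2 * k]]

    names = (
        list(FEATURE_NAMES) if p == len(FEATURE_NAMES) else [f"f{i:03d}" for i in range(p)]
    )
    return FeatureTable(pd.DataFrame(Z, columns=names), labels, groups)
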