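"""Independent brute-force oracles for texture features and ROC cutoffs.

Everything here is written with explicit Python loops, deliberately
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm_matrix(levels: np.ndarray, offset, n_bins: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by looping voxels."""
    counts = np.zeros((n_bins, n_bins), dtype=float)
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                b = levels[u, v, w]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    tot = counts.sum()
    return counts / tot if tot > 0 else counts


def brute_glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features by explicit double loops."""
    n = P.shape[0]
    f: dict[str, float] = {}
    log2 = lambda v: math.log(v, 2)

    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * P[i][j] for i in range(n) for j in range(n))
    var = sum((i + 1 - mu) ** 2 * P[i][j] for i in range(n) for j in range(n))

    f["joint_maximum"] = max(P[i][j] for i in range(n) for j in range(n))
    f["joint_average"] = mu
    f["joint_variance"] = var
    f["joint_entropy"] = -sum(
        P[i][j] * log2(P[i][j]) for i in range(n) for j in range(n) if P[i][j] > 0
    )

    d = [0.0] * n
    s = [0.0] * (2 * n + 1)
    for i in range(n):
        for j in range(n):
            d[abs(i - j)] += P[i][j]
            s[i + j + 2] += P[i][j]
    da = sum(k * d[k] for k in range(n))
    f["difference_average"] = da
    f["difference_variance"] = sum((k - da) ** 2 * d[k] for k in range(n))
    f["difference_entropy"] = -sum(v * log2(v) for v in d if v > 0)
    sa = sum(k * s[k] for k in range(2 * n + 1))
    f["sum_average"] = sa
    f["sum_variance"] = sum((k - sa) ** 2 * s[k] for k in range(2 * n + 1))
    f["sum_entropy"] = -sum(v * log2(v) for v in s if v > 0)

    f["angular_second_moment"] = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    f["contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(n) for j in range(n))
    f["dissimilarity"] = sum(abs(i - j) * P[i][j] for i in range(n) for j in range(n))
    f["inverse_difference"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
    )
    f["inverse_difference_normalized"] = sum(
        P[i][j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n)
    )
    f["inverse_difference_moment"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
    )
    f["inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / n**2) for i in range(n) for j in range(n)
    )
    f["inverse_variance"] = sum(
        P[i][j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
    )
    auto = sum((i + 1) * (j + 1) * P[i][j] for i in range(n) for j in range(n))
    f["correlation"] = (auto - mu * mu) / var if var > 0 else 1.0
    f["autocorrelation"] = auto
    f["cluster_tendency"] = sum(
        (i + j + 2 - 2 * mu) ** 2 * P[i][j] for i in range(n) for j in range(n)
    )
    f["cluster_shade"] = sum(
        (i + j + 2 - 2 * mu) ** 3 * P[i][j] for i in range(n) for j in range(n)
    )
    f["cluster_prominence"] = sum(
        (i + j + 2 - 2 * mu) ** 4 * P[i][j] for i in range(n) for j in range(n)
    )

    hx = -sum(p * log2(p) for p in px if p > 0)
    hxy = f["joint_entropy"]
    hxy1 = -sum(
        P[i][j] * log2(px[i] * px[j])
        for i in range(n)
        for j in range(n)
        if P[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * log2(px[i] * px[j])
        for i in range(n)
        for j in range(n)
        if px[i] * px[j] > 0
    )
    if hx > 0:
        f["information_correlation_1"] = (hxy - hxy1) / hx
        f["information_correlation_2"] = math.sqrt(
            max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
        )
    else:
        f["information_correlation_1"] = 0.0
        f["information_correlation_2"] = 0.0
    return f


def brute_glrlm_matrix(levels: np.ndarray, offset, n_bins: int) -> tuple[np.ndarray, int]:
    """Run-length counts by walking runs voxel-by-voxel; returns (R, n_voxels)."""
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    runs: list[tuple[int, int]] = []

    def inside(x, y, z):
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                # run start: predecessor absent or different
                px, py, pz = x - dx, y - dy, z - dz
                if inside(px, py, pz) and levels[px, py, pz] == a:
                    continue
                length = 1
                u, v, w = x + dx, y + dy, z + dz
                while inside(u, v, w) and levels[u, v, w] == a:
                    length += 1
                    u, v, w = u + dx, v + dy, w + dz
                runs.append((a, length))
    max_len = max((l for _, l in runs), default=1)
    R = np.zeros((n_bins, max_len), dtype=float)
    for a, l in runs:
        R[a - 1, l - 1] += 1
    return R, int((levels > 0).sum())


def brute_glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    n, L = R.shape
    ns = R.sum()
    f: dict[str, float] = {}
    f["short_run_emphasis"] = sum(
        R[i][j] / (j + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["long_run_emphasis"] = sum(
        R[i][j] * (j + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["low_gray_level_run_emphasis"] = sum(
        R[i][j] / (i + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["high_gray_level_run_emphasis"] = sum(
        R[i][j] * (i + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["short_run_low_gray_level_emphasis"] = sum(
        R[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(n) for j in range(L)
    ) / ns
    f["short_run_high_gray_level_emphasis"] = sum(
        R[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["long_run_low_gray_level_emphasis"] = sum(
        R[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    f["long_run_high_gray_level_emphasis"] = sum(
        R[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(n) for j in range(L)
    ) / ns
    ri = [sum(R[i][j] for j in range(L)) for i in range(n)]
    rj = [sum(R[i][j] for i in range(n)) for j in range(L)]
    f["gray_level_non_uniformity"] = sum(v**2 for v in ri) / ns
    f["gray_level_non_uniformity_normalized"] = sum(v**2 for v in ri) / ns**2
    f["run_length_non_uniformity"] = sum(v**2 for v in rj) / ns
    f["run_length_non_uniformity_normalized"] = sum(v**2 for v in rj) / ns**2
    f["run_percentage"] = ns / n_voxels
    mu_i = sum((i + 1) * R[i][j] / ns for i in range(n) for j in range(L))
    mu_j = sum((j + 1) * R[i][j] / ns for i in range(n) for j in range(L))
    f["gray_level_variance"] = sum(
        (i + 1 - mu_i) ** 2 * R[i][j] / ns for i in range(n) for j in range(L)
    )
    f["run_length_variance"] = sum(
        (j + 1 - mu_j) ** 2 * R[i][j] / ns for i in range(n) for j in range(L)
    )
    f["run_entropy"] = -sum(
        (R[i][j] / ns) * math.log(R[i][j] / ns, 2)
        for i in range(n)
        for j in range(L)
        if R[i][j] > 0
    )
    return f


ALL_13_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and next(c for c in (dx, dy, dz) if c != 0) > 0
]


def brute_glcm_averaged(levels: np.ndarray, n_bins: int) -> dict[str, float]:
    per_dir = []
    for off in ALL_13_OFFSETS:
        P = brute_glcm_matrix(levels, off, n_bins)
        if P.sum() > 0:
            per_dir.append(brute_glcm_features(P))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def brute_glrlm_averaged(levels: np.ndarray, n_bins: int) -> dict[str, float]:
    per_dir = []
    for off in ALL_13_OFFSETS:
        R, nv = brute_glrlm_matrix(levels, off, n_bins)
        if R.sum() > 0:
            per_dir.append(brute_glrlm_features(R, nv))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# ROC cutoff oracles (exhaustive threshold search with the same tie rules)

def brute_youden(scores, labels):
    """Exhaustive search over candidate thresholds; returns (cutoff, J)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    u = sorted(set(scores.tolist()))
    cands = [u[0] - 1.0] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [u[-1]]
    best = None
    for c in cands:
        tp = fp = tn = fn = 0
        for s, l in zip(scores, labels):
            if s > c:
                tp, fp = tp + (l == 1), fp + (l == 0)
            else:
                tn, fn = tn + (l == 0), fn + (l == 1)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if best is None or (j, spec) > best[:2]:
            best = (j, spec, c)
    return best[2], best[0]


def brute_npv_max(scores, labels):
    """Exhaustive search; ties by max specificity then lower threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    u = sorted(set(scores.tolist()))
    cands = [u[0] - 1.0] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [u[-1]]
    best = None
    for c in cands:
        tp = fp = tn = fn = 0
        for s, l in zip(scores, labels):
            if s > c:
                tp, fp = tp + (l == 1), fp + (l == 0)
            else:
                tn, fn = tn + (l == 0), fn + (l == 1)
        if tn + fn == 0:
            continue
        npv = tn / (tn + fn)
        spec = tn / (tn + fp)
        if best is None or (npv, spec, -c) > best[:3]:
            best = (npv, spec, -c, c)
    return best[3], best[0]
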