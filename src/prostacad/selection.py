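"""Two-stage feature selection for the aggressiveness classifier.

Stage one is a filter: features are min-max normalized, ranked by
case-resampled bootstrap AUC (orientation-folded so ranking is
direction-free), and pruned so that of any pair with |Pearson rho| above
0.9 only the higher-AUC member survives. Stage two is a wrapper: nested
subsets of the top-n ranked features feed a third-order polynomial-kernel
SVM under stratified, patient-grouped 4-fold cross-validation; the chosen
subset size is the overfitting point — the smallest n at which mean test
accuracy peaks while accuracy at larger n no longer improves. The box
constraint C is then tuned by grid search over 1..50 on the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.svm import SVC

from .exceptions import DegenerateDataError

SVM_KERNEL_PARAMS = dict(kernel="poly", gamma=1.0, coef0=1.0)


@dataclass
class FeatureTable:
    """Lesion-by-feature table with binary labels and patient grouping.

    labels: 1 = high aggressive (GG > 2), 0 = low aggressive (GG <= 2).
    """

    features: pd.DataFrame
    labels: np.ndarray
    group_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary {0, 1}")
        if len(self.labels) != len(self.features):
            raise ValueError("labels/features length mismatch")
        if self.group_id is None:
            self.group_id = np.arange(len(self.labels))
        else:
            self.group_id = np.asarray(self.group_id)

    @property
    def n(self) -> int:
        return len(self.labels)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise DegenerateDataError("both classes must be present")


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned on training rows."""

    minima: dict[str, float]
    maxima: dict[str, float]

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        """Scale columns by the stored training range. Held-out values may
        fall outside [0, 1]; they are deliberately not clipped. Constant
        training columns map to 0."""
        out = {}
        for col in df.columns:
            lo, hi = self.minima[col], self.maxima[col]
            if hi > lo:
                out[col] = (df[col].to_numpy(float) - lo) / (hi - lo)
            else:
                out[col] = np.zeros(len(df))
        return pd.DataFrame(out, index=df.index)

    def to_dict(self) -> dict:
        return {"minima": dict(self.minima), "maxima": dict(self.maxima)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(minima=dict(d["minima"]), maxima=dict(d["maxima"]))


@dataclass
class FSResult:
    """Outcome of ranking, pruning, and wrapper subset selection."""

    ranked_features: list[str]
    aucs: dict[str, float]
    auc_cis: dict[str, tuple[float, float]]
    removed_correlated: list[tuple[str, str, float]]  # (dropped, kept, rho)
    subset_size_n: int
    train_acc_curve: list[float]
    test_acc_curve: list[float]
    best_C: int
    seed: int

    @property
    def subset(self) -> list[str]:
        return self.ranked_features[: self.subset_size_n]

    def to_dict(self) -> dict:
        return {
            "ranked_features": list(self.ranked_features),
            "aucs": {k: float(v) for k, v in self.aucs.items()},
            "auc_cis": {k: [float(a), float(b)] for k, (a, b) in self.auc_cis.items()},
            "removed_correlated": [[d, k, float(r)] for d, k, r in self.removed_correlated],
            "subset_size_n": int(self.subset_size_n),
            "train_acc_curve": [float(x) for x in self.train_acc_curve],
            "test_acc_curve": [float(x) for x in self.test_acc_curve],
            "best_C": int(self.best_C),
            "seed": int(self.seed),
        }


# --------------------------------------------------------------------------
# Normalization

def minmax_fit_apply(table: FeatureTable) -> tuple[FeatureTable, NormalizationParams]:
    """Learn per-feature (min, max) on the table and scale it to [0, 1]."""
    minima = {c: float(table.features[c].min()) for c in table.features.columns}
    maxima = {c: float(table.features[c].max()) for c in table.features.columns}
    params = NormalizationParams(minima=minima, maxima=maxima)
    scaled = params.apply(table.features)
    return FeatureTable(scaled, table.labels.copy(), np.asarray(table.group_id).copy()), params


# --------------------------------------------------------------------------
# AUC ranking

def auc_mann_whitney(x: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected (midrank) Mann-Whitney estimate of the AUC of a
    single feature for the positive class."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("AUC requires both classes")
    r = rankdata(x)
    r1 = r[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def _bootstrap_auc_matrix(
    x: np.ndarray, labels: np.ndarray, n_boot: int, rng: np.random.Generator,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Folded AUC for each of n_boot case-resampled replicates (vectorized
    midrank computation). Replicates missing a class are redrawn."""
    n = len(labels)
    if indices is None:
        indices = rng.integers(0, n, size=(n_boot, n))
        for _ in range(100):
            bad = np.flatnonzero(
                (labels[indices].sum(axis=1) == 0) | (labels[indices].sum(axis=1) == n)
            )
            if bad.size == 0:
                break
            indices[bad] = rng.integers(0, n, size=(bad.size, n))
    lab_b = labels[indices]
    ranks = rankdata(x[indices], axis=1)
    n1 = lab_b.sum(axis=1)
    n0 = n - n1
    r1 = (ranks * lab_b).sum(axis=1)
    auc = (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)
    return np.maximum(auc, 1.0 - auc)


def bootstrap_auc(
    feature: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Bootstrap AUC of one feature: mean folded AUC over case-resampled
    replicates with a percentile 95% CI. Folding (max of AUC, 1-AUC) makes
    the ranking indifferent to whether high or low values mark aggression.
    """
    labels = np.asarray(labels, dtype=int)
    if n_boot < 1:
        a = auc_mann_whitney(feature, labels)
        a = max(a, 1 - a)
        return a, a, a
    rng = np.random.default_rng(seed)
    aucs = _bootstrap_auc_matrix(np.asarray(feature, float), labels, n_boot, rng, indices)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.mean()), float(lo), float(hi)


def rank_features_by_auc(
    table: FeatureTable, n_boot: int = 1000, seed: int = 0
) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Bootstrap AUC (and CI) per feature, sharing one set of case
    resamples across features."""
    table.require_both_classes()
    rng = np.random.default_rng(seed)
    n = table.n
    indices = rng.integers(0, n, size=(n_boot, n))
    lab = table.labels
    for _ in range(100):
        s = lab[indices].sum(axis=1)
        bad = np.flatnonzero((s == 0) | (s == n))
        if bad.size == 0:
            break
        indices[bad] = rng.integers(0, n, size=(bad.size, n))
    aucs, cis = {}, {}
    for col in table.features.columns:
        a, lo, hi = bootstrap_auc(
            table.features[col].to_numpy(float), lab, n_boot=n_boot, seed=0, indices=indices
        )
        aucs[col] = a
        cis[col] = (lo, hi)
    return aucs, cis


# --------------------------------------------------------------------------
# Correlation pruning

def prune_correlated(
    table: FeatureTable, aucs: dict[str, float], rho_max: float = 0.9
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy removal of redundant features.

    Feature pairs with |Pearson rho| strictly above ``rho_max`` are visited
    in descending |rho| (ties broken by canonical column order); the
    lower-AUC member is dropped (AUC ties broken toward keeping the earlier
    column). Pairs whose members were already dropped are skipped.
    """
    cols = list(table.features.columns)
    if len(cols) < 2:
        return cols, []
    corr = np.corrcoef(table.features.to_numpy(float), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho = abs(corr[i, j])
            # strict "higher than" with a guard for float round-off so a
            # correlation numerically at the limit is not pruned
            if rho > rho_max + 1e-12:
                pairs.append((rho, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    removed: list[tuple[str, str, float]] = []
    for rho, i, j in pairs:
        a, b = cols[i], cols[j]
        if a in dropped or b in dropped:
            continue
        # drop the lower-AUC member; on an exact tie keep the earlier column
        loser, keeper = (b, a) if aucs[a] >= aucs[b] else (a, b)
        dropped.add(loser)
        removed.append((loser, keeper, float(rho)))
    kept = [c for c in cols if c not in dropped]
    return kept, removed


# --------------------------------------------------------------------------
# Cross-validation folds

def make_cv_folds(
    labels: np.ndarray, groups: np.ndarray, k_folds: int, seed: int, max_attempts: int = 10
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, patient-grouped k-fold split with both classes present
    in every train and test part; reshuffles with derived seeds on failure.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    for attempt in range(max_attempts):
        cv = StratifiedGroupKFold(n_splits=k_folds, shuffle=True, random_state=(seed + attempt) % (2**31))
        folds = list(cv.split(np.zeros((len(labels), 1)), labels, groups))
        ok = all(
            len(np.unique(labels[tr])) == 2 and len(np.unique(labels[te])) == 2
            for tr, te in folds
        )
        if ok:
            return folds
    raise DegenerateDataError(
        f"could not stratify {k_folds} folds with both classes after {max_attempts} attempts"
    )


def _make_svm(C: float, degree: int = 3) -> SVC:
    return SVC(C=C, degree=degree, **SVM_KERNEL_PARAMS)


def _cv_accuracies(
    X: np.ndarray, y: np.ndarray, folds, C: float, degree: int = 3
) -> tuple[float, float]:
    """Mean train / mean test accuracy of the polynomial SVM over folds,
    predictions at the standard 0.5 decision threshold."""
    tr_accs, te_accs = [], []
    for tr, te in folds:
        clf = _make_svm(C, degree)
        clf.fit(X[tr], y[tr])
        tr_accs.append(float((clf.predict(X[tr]) == y[tr]).mean()))
        te_accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(tr_accs)), float(np.mean(te_accs))


def choose_overfitting_point(test_acc_curve: list[float]) -> int:
    """Smallest subset size n (1-based) at which mean test accuracy is
    maximal and does not improve at n+1 or n+2 — the point where the
    train curve keeps rising while the test curve stops."""
    curve = np.asarray(test_acc_curve, dtype=float)
    best = curve.max()
    for i, v in enumerate(curve):
        if v >= best - 1e-12:
            nxt = curve[i + 1 : i + 3]
            if all(w <= v + 1e-12 for w in nxt):
                return i + 1
    return int(np.argmax(curve)) + 1  # unreachable fallback


def wrapper_select(
    table: FeatureTable,
    k_folds: int = 4,
    max_n: int | None = None,
    svm_degree: int = 3,
    C: float = 1.0,
    seed: int = 0,
    n_boot: int = 1000,
    rho_max: float = 0.9,
    aucs: dict[str, float] | None = None,
    auc_cis: dict[str, tuple[float, float]] | None = None,
) -> FSResult:
    """Full stage-one + stage-two selection on a normalized table.

    Ranks by bootstrap AUC, prunes |rho| > rho_max, then grows nested
    top-n subsets through the cross-validated SVM and picks the
    overfitting point. Fully deterministic under ``seed``.
    """
    table.require_both_classes()
    if aucs is None:
        aucs, auc_cis = rank_features_by_auc(table, n_boot=n_boot, seed=seed)
    if auc_cis is None:
        auc_cis = {k: (v, v) for k, v in aucs.items()}

    kept, removed = prune_correlated(table, aucs, rho_max=rho_max)
    ranked = sorted(kept, key=lambda c: (-aucs[c], list(table.features.columns).index(c)))
    if max_n is None:
        max_n = len(ranked)
    max_n = min(max_n, len(ranked))
    if max_n < 1:
        raise DegenerateDataError("no features survive pruning")

    folds = make_cv_folds(table.labels, table.group_id, k_folds, seed)
    y = table.labels
    train_curve, test_curve = [], []
    for n in range(1, max_n + 1):
        X = table.features[ranked[:n]].to_numpy(float)
        tr, te = _cv_accuracies(X, y, folds, C=C, degree=svm_degree)
        train_curve.append(tr)
        test_curve.append(te)
    n_chosen = choose_overfitting_point(test_curve)

    best_C = grid_search_C(
        table, ranked[:n_chosen], k_folds=k_folds, seed=seed, folds=folds, degree=svm_degree
    )
    return FSResult(
        ranked_features=ranked,
        aucs={k: aucs[k] for k in table.features.columns},
        auc_cis={k: auc_cis[k] for k in table.features.columns},
        removed_correlated=removed,
        subset_size_n=n_chosen,
        train_acc_curve=train_curve,
        test_acc_curve=test_curve,
        best_C=best_C,
        seed=seed,
    )


def grid_search_C(
    table: FeatureTable,
    subset: list[str],
    C_grid=range(1, 51),
    k_folds: int = 4,
    seed: int = 0,
    folds=None,
    degree: int = 3,
) -> int:
    """Box-constraint grid search on the chosen subset.

    Evaluates every C on identical folds and returns the smallest C
    attaining the maximal mean CV test accuracy (ties resolved toward
    stronger regularization)."""
    if not subset:
        raise ValueError("subset must be nonempty")
    if folds is None:
        folds = make_cv_folds(table.labels, table.group_id, k_folds, seed)
    X = table.features[list(subset)].to_numpy(float)
    y = table.labels
    best_C, best_acc = None, -1.0
    for C in C_grid:
        _, te = _cv_accuracies(X, y, folds, C=float(C), degree=degree)
        if te > best_acc + 1e-12:
            best_acc, best_C = te, int(C)
    return best_C
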