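"""Final classifier, radiomics score, ROC cutoffs, and three-tier banding.

A third-order polynomial-kernel SVM is fitted on the selected feature
subset; its decision values are mapped to a [0, 1] radiomics score by a
Platt-style sigmoid fitted on the training decision values (monotone, so
score order equals decision-value order). Two operating points are derived
from the training scores: the Youden cutoff (maximal sensitivity +
specificity - 1) and the NPV-maximizing cutoff, which with continuous
scores places every training positive above it (zero false negatives).
The score is banded into three levels: aggressive above the Youden cutoff,
indeterminate within 15% below it, indolent underneath.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, SchemaError
from .selection import FeatureTable, NormalizationParams, _make_svm

POSITIVE_CLASS = 1  # high aggressive, GG > 2


# --------------------------------------------------------------------------
# Platt sigmoid calibration

def platt_fit(decisions: np.ndarray, labels: np.ndarray, max_iter: int = 200) -> tuple[float, float]:
    """Fit sigmoid P(y=1|d) = 1 / (1 + exp(A d + B)) by regularized
    maximum likelihood (Platt's targets (N+ + 1)/(N+ + 2) and 1/(N- + 2)),
    Newton iterations with backtracking. Deterministic."""
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("calibration requires both classes")
    hi, lo = (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0)
    t = np.where(y == 1, hi, lo)

    A, B = 0.0, float(np.log((n0 + 1.0) / (n1 + 1.0)))

    def objective(a, b):
        z = a * d + b
        # stable log(1 + exp(z)) pieces
        pos = z >= 0
        f = np.empty_like(z)
        f[pos] = t[pos] * z[pos] + np.log1p(np.exp(-z[pos]))
        f[~pos] = (t[~pos] - 1.0) * z[~pos] + np.log1p(np.exp(z[~pos]))
        return float(f.sum())

    fval = objective(A, B)
    for _ in range(max_iter):
        z = A * d + B
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        w = p * (1.0 - p)
        # gradient of sum(t*z + log(1+e^-z)) wrt (A,B)
        g = t - p
        g1 = float((g * d).sum())
        g2 = float(g.sum())
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float((w * d * d).sum()) + 1e-12
        h12 = float((w * d).sum())
        h22 = float(w.sum()) + 1e-12
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g1 - h12 * g2) / det
        dB = -(h11 * g2 - h12 * g1) / det
        step = 1.0
        while step >= 1e-10:
            nA, nB = A + step * dA, B + step * dB
            nf = objective(nA, nB)
            if nf < fval + 1e-12:
                A, B, fval = nA, nB, nf
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def platt_apply(decisions: np.ndarray, A: float, B: float) -> np.ndarray:
    z = np.clip(A * np.asarray(decisions, float) + B, -500, 500)
    return np.clip(1.0 / (1.0 + np.exp(z)), 0.0, 1.0)


# --------------------------------------------------------------------------
# Trained scorer

@dataclass
class TrainedScorer:
    """Everything needed to score a new lesion: normalization, feature
    subset, the fitted kernel machine, and the sigmoid calibration."""

    normalization: NormalizationParams
    subset: list[str]
    kernel_degree: int
    C: float
    gamma: float
    coef0: float
    support_vectors: np.ndarray  # (n_sv, len(subset))
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    platt_a: float
    platt_b: float
    seed: int = 0
    config_hash: str = ""

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = (self.gamma * X @ self.support_vectors.T + self.coef0) ** self.kernel_degree
        return K @ self.dual_coef + self.intercept

    def score_frame(self, features: pd.DataFrame) -> np.ndarray:
        """Score each row of a raw (unnormalized) feature table."""
        missing = [c for c in self.subset if c not in features.columns]
        if missing:
            raise SchemaError(f"missing features required by the model: {missing}")
        norm = self.normalization.apply(features[self.subset])
        dec = self.decision_function(norm.to_numpy(float))
        return platt_apply(dec, self.platt_a, self.platt_b)

    def to_dict(self) -> dict:
        return {
            "normalization": self.normalization.to_dict(),
            "subset": list(self.subset),
            "kernel_degree": int(self.kernel_degree),
            "C": float(self.C),
            "gamma": float(self.gamma),
            "coef0": float(self.coef0),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": float(self.intercept),
            "platt_a": float(self.platt_a),
            "platt_b": float(self.platt_b),
            "seed": int(self.seed),
            "config_hash": self.config_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedScorer":
        return cls(
            normalization=NormalizationParams.from_dict(d["normalization"]),
            subset=list(d["subset"]),
            kernel_degree=int(d["kernel_degree"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            coef0=float(d["coef0"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            seed=int(d.get("seed", 0)),
            config_hash=d.get("config_hash", ""),
        )


def train_scorer(
    table: FeatureTable,
    subset: list[str],
    C: float,
    seed: int = 0,
    normalization: NormalizationParams | None = None,
    config_hash: str = "",
) -> TrainedScorer:
    """Fit the polynomial-kernel classifier on a normalized table and
    calibrate its decision values to [0, 1] scores.

    ``normalization`` is the min-max transform that produced the table
    (stored for scoring raw inputs); identity if omitted.
    """
    table.require_both_classes()
    if not subset:
        raise ValueError("subset must be nonempty")
    X = table.features[list(subset)].to_numpy(float)
    y = table.labels
    clf = _make_svm(float(C), degree=3)
    clf.fit(X, y)
    dec = clf.decision_function(X)
    A, B = platt_fit(dec, y)
    if normalization is None:
        normalization = NormalizationParams(
            minima={c: 0.0 for c in subset}, maxima={c: 1.0 for c in subset}
        )
    return TrainedScorer(
        normalization=normalization,
        subset=list(subset),
        kernel_degree=3,
        C=float(C),
        gamma=clf._gamma if hasattr(clf, "_gamma") else 1.0,
        coef0=clf.coef0,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        platt_a=A,
        platt_b=B,
        seed=seed,
        config_hash=config_hash,
    )


def score(model: TrainedScorer, features) -> float:
    """Radiomics score in [0, 1] for one lesion.

    ``features`` may be a FeatureVector, a mapping, or a pandas Series.
    """
    if hasattr(features, "values") and isinstance(getattr(features, "values"), dict):
        mapping = features.values
    elif isinstance(features, pd.Series):
        mapping = features.to_dict()
    else:
        mapping = dict(features)
    missing = [c for c in model.subset if c not in mapping]
    if missing:
        raise SchemaError(f"missing features required by the model: {missing}")
    frame = pd.DataFrame([{c: float(mapping[c]) for c in model.subset}])
    return float(model.score_frame(frame)[0])


# --------------------------------------------------------------------------
# ROC cutoffs

def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores, plus a cutoff below
    every score (all called positive) and one at the maximum (all called
    negative). Positives are scores strictly above the cutoff."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate(([u[0] - 1.0], mids, [u[-1]]))


def _confusion_at(scores, labels, cutoff):
    pred = scores > cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return tp, fp, tn, fn


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1 over
    all candidate thresholds; ties resolved toward higher specificity
    (the larger cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("Youden cutoff requires both classes")
    best = None
    for c in _candidate_cutoffs(scores):
        tp, fp, tn, fn = _confusion_at(scores, labels, c)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1]


def npv_max_cutoff(scores, labels) -> float:
    """Cutoff maximizing the negative predictive value among thresholds
    making at least one negative call; ties resolved by maximal
    specificity (more negatives called), then by the lower threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("NPV cutoff requires both classes")
    best = None
    for c in _candidate_cutoffs(scores):
        tp, fp, tn, fn = _confusion_at(scores, labels, c)
        if tn + fn == 0:
            continue
        npv = tn / (tn + fn)
        spec = tn / (tn + fp)
        key = (npv, spec, -float(c))
        if best is None or key > best[0]:
            best = (key, float(c))
    if best is None:
        raise DegenerateDataError("no threshold yields a negative call")
    return best[1]


# --------------------------------------------------------------------------
# Three-tier banding

@dataclass
class CutoffSet:
    """The two training cutoffs plus the indeterminate band width."""

    youden: float
    npv_max: float
    band_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.band_fraction < 1.0):
            raise ValueError("band_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "youden": float(self.youden),
            "npv_max": float(self.npv_max),
            "band_fraction": float(self.band_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffSet":
        return cls(**d)


@dataclass
class AggScore:
    """Three-level aggressiveness call for one lesion."""

    level: str  # "indolent" | "indeterminate" | "aggressive"
    raw_score: float
    normalized_score: float  # raw - Youden cutoff


def assign_agg_score(raw: float, cutoffs: CutoffSet) -> AggScore:
    """Band a radiomics score.

    aggressive: raw > youden; indeterminate: within the band_fraction
    window directly below the cutoff; indolent: at or below
    (1 - band_fraction) * youden. The three bands partition [0, 1] and the
    level is monotone in the raw score."""
    yc = cutoffs.youden
    lo = (1.0 - cutoffs.band_fraction) * yc
    if raw > yc:
        level = "aggressive"
    elif raw > lo:
        level = "indeterminate"
    else:
        level = "indolent"
    return AggScore(level=level, raw_score=float(raw), normalized_score=float(raw - yc))


def waterfall_data(scores, labels, cutoff: float) -> pd.DataFrame:
    """Cutoff-normalized scores sorted descending, with class labels —
    the plotting substrate for a waterfall chart. The sign of the
    normalized score equals the aggressive / non-aggressive call."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    df = pd.DataFrame({"normalized_score": scores - cutoff, "label": labels})
    return df.sort_values("normalized_score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


# --------------------------------------------------------------------------
# Model file (scorer + cutoffs) with integrity hash

MODEL_SCHEMA_VERSION = 1


def _payload_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def save_model(path, scorer: TrainedScorer, cutoffs: CutoffSet) -> None:
    """Write scorer + cutoffs as a single versioned JSON file with a
    content hash for tamper detection."""
    payload = {
        "scorer": scorer.to_dict(),
        "cutoffs": cutoffs.to_dict(),
    }
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "payload": payload,
        "sha256": _payload_hash(payload),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> tuple[TrainedScorer, CutoffSet]:
    """Load and verify a model file; raises SchemaError on version or
    integrity mismatch."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"unreadable model file {path}: {exc}") from exc
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    payload = doc.get("payload", {})
    if _payload_hash(payload) != doc.get("sha256"):
        raise SchemaError("model file integrity check failed (hash mismatch)")
    return TrainedScorer.from_dict(payload["scorer"]), CutoffSet.from_dict(payload["cutoffs"])
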