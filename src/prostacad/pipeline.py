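"""End-to-end orchestration: detect -> extract -> select -> train -> cut.

``run_train`` drives the full training path on a cohort of cases and
writes the model, the feature-selection record, and an evaluation report;
``run_score`` applies a saved model to new feature rows.
``train_from_table`` is the table-level core shared by the imaging path
and table-only studies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import DetectionConfig, extract_candidates, filter_voxels, select_lesion
from .exceptions import DegenerateDataError, ProstacadError
from .imaging_io import CaseBundle, Mask3D
from .model import (
    CutoffSet,
    TrainedScorer,
    assign_agg_score,
    load_model,
    npv_max_cutoff,
    save_model,
    train_scorer,
    youden_cutoff,
)
from .preprocess import PreprocessConfig
from .selection import (
    FeatureTable,
    FSResult,
    minmax_fit_apply,
    rank_features_by_auc,
    wrapper_select,
)
from .stats import confusion_metrics, delong_auc
from .texture import FEATURE_NAMES, extract_feature_vector

log = logging.getLogger("prostacad")


@dataclass
class PipelineConfig:
    """All pipeline constants in one serializable object."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    rho_max: float = 0.9
    k_folds: int = 4
    c_grid_max: int = 50
    n_boot: int = 1000
    band_fraction: float = 0.15
    max_n: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "detection": self.detection.to_dict(),
            "rho_max": self.rho_max,
            "k_folds": self.k_folds,
            "c_grid_max": self.c_grid_max,
            "n_boot": self.n_boot,
            "band_fraction": self.band_fraction,
            "max_n": self.max_n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["preprocess"] = PreprocessConfig.from_dict(d.get("preprocess", {}))
        d["detection"] = DetectionConfig.from_dict(d.get("detection", {}))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# Per-case imaging front end

def detect_and_segment(
    case_id: str, bundle: CaseBundle, reference: Mask3D, config: PipelineConfig
) -> Mask3D:
    """Candidate detection plus overlap-surrogate lesion confirmation for
    one case; returns the selected candidate's mask."""
    kept = filter_voxels(bundle, config.detection)
    candidates = extract_candidates(kept, config.detection)
    chosen = select_lesion(candidates, reference)
    if chosen is None:
        raise DegenerateDataError(f"[{case_id}] detection produced no candidate lesion")
    return chosen.to_mask(kept)


def extract_cohort_features(
    cases: list[tuple[str, CaseBundle, Mask3D, int]],
    config: PipelineConfig,
    use_detection: bool = True,
) -> FeatureTable:
    """Feature table for a cohort of (case_id, bundle, truth mask, label).

    With ``use_detection`` the lesion mask comes from the candidate
    pipeline (truth mask acting as the confirmation reference); otherwise
    the truth mask is used directly."""
    rows, labels, groups, ids = [], [], [], []
    for case_id, bundle, truth, label in cases:
        try:
            mask = (
                detect_and_segment(case_id, bundle, truth, config) if use_detection else truth
            )
            fv = extract_feature_vector(bundle, mask, config.preprocess)
        except ProstacadError as exc:
            raise type(exc)(f"[{case_id}] feature extraction failed: {exc}") from exc
        log.info("extracted features case=%s label=%d", case_id, label)
        rows.append(fv.values)
        labels.append(label)
        groups.append(case_id)
        ids.append(case_id)
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=ids)
    return FeatureTable(frame, np.asarray(labels), np.asarray(groups))


# --------------------------------------------------------------------------
# Table-level training core

@dataclass
class TrainingResult:
    scorer: TrainedScorer
    cutoffs: CutoffSet
    fs_result: FSResult
    train_scores: np.ndarray
    table: FeatureTable


def train_from_table(table: FeatureTable, config: PipelineConfig) -> TrainingResult:
    """Normalize, rank, prune, wrap, grid-search, fit, and cut."""
    table.require_both_classes()
    normalized, norm_params = minmax_fit_apply(table)
    log.info("normalized %d rows x %d features", table.n, table.features.shape[1])
    aucs, cis = rank_features_by_auc(normalized, n_boot=config.n_boot, seed=config.seed)
    fs = wrapper_select(
        normalized,
        k_folds=config.k_folds,
        max_n=config.max_n,
        C=1.0,
        seed=config.seed,
        rho_max=config.rho_max,
        aucs=aucs,
        auc_cis=cis,
    )
    log.info("selected n=%d features, best C=%d", fs.subset_size_n, fs.best_C)
    scorer = train_scorer(
        normalized,
        fs.subset,
        C=fs.best_C,
        seed=config.seed,
        normalization=norm_params,
        config_hash=config.config_hash(),
    )
    train_scores = scorer.score_frame(table.features)
    cutoffs = CutoffSet(
        youden=youden_cutoff(train_scores, table.labels),
        npv_max=npv_max_cutoff(train_scores, table.labels),
        band_fraction=config.band_fraction,
    )
    log.info("cutoffs youden=%.4f npv_max=%.4f", cutoffs.youden, cutoffs.npv_max)
    return TrainingResult(scorer, cutoffs, fs, train_scores, table)


def evaluation_report(scores, labels, cutoffs: CutoffSet) -> dict:
    """AUC plus confusion metrics at both operating points."""
    return {
        "auc": delong_auc(scores, labels),
        "at_youden_cutoff": confusion_metrics(scores, labels, cutoffs.youden).to_dict(),
        "at_npv_max_cutoff": confusion_metrics(scores, labels, cutoffs.npv_max).to_dict(),
        "cutoffs": cutoffs.to_dict(),
    }


# --------------------------------------------------------------------------
# File-level entry points

def run_train(
    config: PipelineConfig,
    cases: list[tuple[str, CaseBundle, Mask3D, int]] | None,
    out_dir: str,
    table: FeatureTable | None = None,
    use_detection: bool = True,
) -> TrainingResult:
    """Train on an imaging cohort (or a precomputed feature table) and
    write model.json, fs.json, and report.json into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    if table is None:
        if cases is None:
            raise ValueError("provide either cases or a feature table")
        table = extract_cohort_features(cases, config, use_detection=use_detection)
    result = train_from_table(table, config)
    save_model(os.path.join(out_dir, "model.json"), result.scorer, result.cutoffs)
    with open(os.path.join(out_dir, "fs.json"), "w") as fh:
        json.dump(result.fs_result.to_dict(), fh, indent=1)
    report = evaluation_report(result.train_scores, table.labels, result.cutoffs)
    report["config"] = config.to_dict()
    report["config_hash"] = config.config_hash()
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    curve = pd.DataFrame(
        {
            "n_features": np.arange(1, len(result.fs_result.test_acc_curve) + 1),
            "train_accuracy": result.fs_result.train_acc_curve,
            "test_accuracy": result.fs_result.test_acc_curve,
        }
    )
    curve.to_csv(os.path.join(out_dir, "accuracy_vs_n.csv"), index=False)
    return result


def run_score(model_path: str, features: pd.DataFrame) -> pd.DataFrame:
    """Score feature rows with a saved model: raw score, cutoff-normalized
    score, and the three-level call per lesion."""
    scorer, cutoffs = load_model(model_path)
    raw = scorer.score_frame(features)
    levels = [assign_agg_score(float(r), cutoffs).level for r in raw]
    return pd.DataFrame(
        {
            "raw_score": raw,
            "normalized_score": raw - cutoffs.youden,
            "agg_score": levels,
        },
        index=features.index,
    )
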