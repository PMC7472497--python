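"""SVM-RBF training, leave-one-patient-out validation, and the final model.

The window classifier is a support vector machine with a radial basis
function kernel, fit on z-scored features (standardization parameters come
from the training windows only). Validation is leave-one-patient-out (LOPO):
each fold reruns the full feature-selection procedure on the remaining
subjects, trains, and evaluates on the held-out subject's test-role windows,
so no information from the held-out patient leaks into their fold's model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import selection
from .episodes_metrics import WindowMetrics, window_metrics
from .selection import SelectionResult

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0
DEFAULT_GAMMA = "scale"
ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class TrainedModel:
    """A fitted window classifier with its standardization and feature ids."""

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    C: float
    gamma: float | str
    svc: SVC | None = None
    seed: int | None = None
    subjects: list[str] = field(default_factory=list)
    # serialized decision-function payload (used when svc is None)
    _support_vectors: np.ndarray | None = None
    _dual_coef: np.ndarray | None = None
    _intercept: float = 0.0
    _gamma_value: float = 1.0

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.feature_ids].to_numpy(float)
        return (Z - self.mean) / self.sd

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Signed distance to the decision boundary (positive = FOG)."""
        Z = self._standardize(X)
        if self.svc is not None:
            return self.svc.decision_function(Z)
        sq = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self._support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self._support_vectors.T
        )
        K = np.exp(-self._gamma_value * np.maximum(sq, 0.0))
        return K @ self._dual_coef.ravel() + self._intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_scores(X) > 0

    def to_json(self, path: str | Path | None = None) -> dict:
        if self.svc is None:
            raise ValueError("model has no fitted SVC to serialize")
        payload = {
            "feature_ids": self.feature_ids,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "C": self.C,
            "gamma": self.gamma,
            "gamma_value": float(self.svc._gamma),
            "support_vectors": self.svc.support_vectors_.tolist(),
            "dual_coef": self.svc.dual_coef_.tolist(),
            "intercept": float(self.svc.intercept_[0]),
            "seed": self.seed,
            "subjects": self.subjects,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "TrainedModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            feature_ids=list(d["feature_ids"]),
            mean=np.asarray(d["mean"], float),
            sd=np.asarray(d["sd"], float),
            C=d["C"],
            gamma=d["gamma"],
            svc=None,
            seed=d.get("seed"),
            subjects=list(d.get("subjects", [])),
            _support_vectors=np.asarray(d["support_vectors"], float),
            _dual_coef=np.asarray(d["dual_coef"], float),
            _intercept=float(d["intercept"]),
            _gamma_value=float(d["gamma_value"]),
        )


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    ids: Sequence[str] | None = None,
    C: float = DEFAULT_C,
    gamma: float | str = DEFAULT_GAMMA,
    seed: int | None = None,
) -> TrainedModel:
    """Standardize and fit an SVM-RBF on the given feature columns.

    The class imbalance is handled upstream by the asymmetric window
    overlap, so no class weighting is applied here.
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training requires windows from both classes")
    ids = list(ids) if ids is not None else list(X.columns)
    Z = X[ids].to_numpy(float)
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    svc = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
    svc.fit((Z - mean) / sd, y.astype(int))
    return TrainedModel(feature_ids=ids, mean=mean, sd=sd, C=C, gamma=gamma,
                        svc=svc, seed=seed)


@dataclass
class LopoConfig:
    """Knobs of the LOPO loop and per-fold selection."""

    C: float = DEFAULT_C
    gamma: float | str = DEFAULT_GAMMA
    max_k: int | None = selection.DEFAULT_MAX_K
    inner_folds: int = selection.INNER_FOLDS
    select_features: bool = True
    seed: int = 0


@dataclass
class FoldResult:
    subject: str
    metrics: WindowMetrics
    selection: SelectionResult | None
    roc_tpr_grid: np.ndarray  # sensitivity at ROC_GRID false-positive rates


@dataclass
class LopoReport:
    folds: list[FoldResult]

    @property
    def subjects(self) -> list[str]:
        return [f.subject for f in self.folds]

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(f.metrics, attr) for f in self.folds], float)

    def mean_metrics(self) -> dict[str, float]:
        out = {}
        for m in ("sensitivity", "specificity", "accuracy"):
            v = self._vals(m)
            out[f"mean_{m}"] = float(np.mean(v))
            out[f"sd_{m}"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        aucs = [f.metrics.auc for f in self.folds if f.metrics.auc is not None]
        out["mean_auc"] = float(np.mean(aucs)) if aucs else float("nan")
        return out

    def mean_roc(self) -> tuple[np.ndarray, np.ndarray]:
        """Vertical (threshold-averaged) mean ROC: TPR averaged on an FPR grid."""
        curves = [f.roc_tpr_grid for f in self.folds if f.roc_tpr_grid is not None]
        if not curves:
            return ROC_GRID, np.full_like(ROC_GRID, np.nan)
        return ROC_GRID, np.mean(np.vstack(curves), axis=0)

    def mean_roc_auc(self) -> float:
        fpr, tpr = self.mean_roc()
        return float(np.trapezoid(tpr, fpr))

    def optimal_operating_point(self) -> tuple[float, float]:
        """ROC point of the mean curve nearest (0, 1): (FPR, TPR)."""
        fpr, tpr = self.mean_roc()
        d = np.hypot(fpr, 1.0 - tpr)
        i = int(np.argmin(d))
        return float(fpr[i]), float(tpr[i])

    def fold_selections(self) -> list[SelectionResult]:
        return [f.selection for f in self.folds if f.selection is not None]


def _interp_roc(scores: np.ndarray, truth: np.ndarray) -> np.ndarray | None:
    """Per-fold ROC interpolated onto the common FPR grid."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        return None
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return np.interp(ROC_GRID, fpr, tpr)


def select_and_train(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    cfg: LopoConfig,
) -> tuple[TrainedModel, SelectionResult | None]:
    """Run screen -> MRMR -> count choice on a training cohort, then fit."""
    sel: SelectionResult | None = None
    ids = list(X.columns)
    if cfg.select_features:
        screened = selection.screen_ttest(X, y)
        if not screened:
            logger.warning("screening retained no features; falling back to all")
            screened = ids
        ranking = selection.mrmr_rank(X, y, screened)
        trainer = lambda Xt, yt: train(Xt, yt, C=cfg.C, gamma=cfg.gamma, seed=cfg.seed)
        sel = selection.choose_count(
            ranking, X, y, subjects, trainer,
            n_folds=cfg.inner_folds, max_k=cfg.max_k, screened_ids=screened,
        )
        ids = sel.chosen_ids
    model = train(X, y, ids, C=cfg.C, gamma=cfg.gamma, seed=cfg.seed)
    return model, sel


def lopo_validate(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    train_subjects: np.ndarray,
    eval_X: pd.DataFrame,
    eval_y: np.ndarray,
    eval_subjects: np.ndarray,
    cfg: LopoConfig | None = None,
) -> LopoReport:
    """Leave-one-patient-out validation with per-fold feature selection.

    ``train_*`` hold the train-role (asymmetric-overlap) windows of the
    training cohort; ``eval_*`` hold the same subjects' test-role (uniform
    50% overlap) windows, on which each held-out fold is scored.
    """
    cfg = cfg or LopoConfig()
    train_subjects = np.asarray(train_subjects)
    eval_subjects = np.asarray(eval_subjects)
    train_y = np.asarray(train_y, dtype=bool)
    eval_y = np.asarray(eval_y, dtype=bool)
    subjects = sorted(set(train_subjects))
    if len(subjects) < 3:
        raise ValueError("LOPO requires at least 3 subjects")
    folds: list[FoldResult] = []
    for subj in subjects:
        held_eval = eval_subjects == subj
        if not held_eval.any():
            logger.warning("subject %s has no evaluation windows; skipped", subj)
            continue
        m_tr = train_subjects != subj
        model, sel = select_and_train(
            train_X.loc[m_tr], train_y[m_tr], train_subjects[m_tr], cfg
        )
        scores = model.decision_scores(eval_X.loc[held_eval])
        pred = scores > 0
        truth = eval_y[held_eval]
        metrics = window_metrics(pred, truth, scores)
        folds.append(
            FoldResult(
                subject=str(subj),
                metrics=metrics,
                selection=sel,
                roc_tpr_grid=_interp_roc(scores, truth),
            )
        )
    return LopoReport(folds=folds)


def build_final_model(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    train_subjects: np.ndarray,
    lopo_report: LopoReport,
    cfg: LopoConfig | None = None,
) -> tuple[TrainedModel, SelectionResult]:
    """Train the final model on the whole training cohort.

    Features are ordered by their commonness across the LOPO folds'
    selections, the count is chosen by minimum subject-wise training-cohort
    misclassification error over ranking prefixes, and the SVM is refit on
    all training subjects.
    """
    cfg = cfg or LopoConfig()
    ranking = selection.commonness_rank(lopo_report.fold_selections())
    if not ranking:
        raise ValueError("empty commonness ranking")
    trainer = lambda Xt, yt: train(Xt, yt, C=cfg.C, gamma=cfg.gamma, seed=cfg.seed)
    sel = selection.choose_count(
        ranking, train_X, np.asarray(train_y, bool), np.asarray(train_subjects),
        trainer, n_folds=cfg.inner_folds, max_k=cfg.max_k, screened_ids=ranking,
    )
    model = train(train_X, train_y, sel.chosen_ids, C=cfg.C, gamma=cfg.gamma, seed=cfg.seed)
    model.subjects = sorted(set(map(str, train_subjects)))
    return model, sel
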