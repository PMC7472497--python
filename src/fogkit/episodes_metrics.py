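"""Episode reconstruction, derived outcomes, and window-level metrics.

Overlapping test-window predictions are fused into a per-sample binary
timeline by majority vote over the windows covering each sample (ties count
as FOG, favoring sensitivity), converted to intervals, and cleaned with the
same merge/drop rules applied to the ground-truth annotations, so predicted
and true episode sets are directly comparable. The derived outcomes are
percent time frozen, total frozen time, and episode count.

Window metrics follow the clinical-evaluation definitions: sensitivity is
the fraction of FOG windows detected, specificity the fraction of non-FOG
windows rejected; a recording with no FOG windows scores 100% sensitivity
by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .preprocess import WINDOW_LENGTH_S, clean_annotations
from .signal_model import AnnotationTrack


class EpisodeSource(str, Enum):
    ANNOTATION = "annotation"
    PREDICTION = "prediction"


@dataclass
class EpisodeSet:
    """Cleaned FOG intervals, either ground truth or reconstructed."""

    track: AnnotationTrack
    source: EpisodeSource = EpisodeSource.PREDICTION

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class DerivedOutcomes:
    percent_time_frozen: float
    total_time_frozen: float
    n_episodes: int


@dataclass
class WindowMetrics:
    """Window-level confusion counts and rates (percent scale)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None

    @property
    def oop(self) -> tuple[float, float] | None:
        """ROC point nearest (0, 1) as (FPR, TPR)."""
        if self.roc_fpr is None:
            return None
        d = np.hypot(self.roc_fpr, 1.0 - self.roc_tpr)
        i = int(np.argmin(d))
        return float(self.roc_fpr[i]), float(self.roc_tpr[i])


def windows_to_episodes(
    starts: Sequence[float],
    predictions: Sequence[bool],
    duration_s: float,
    fs: float = 128.0,
    length_s: float = WINDOW_LENGTH_S,
) -> EpisodeSet:
    """Fuse overlapping window predictions into cleaned FOG episodes.

    Per-sample majority vote over covering windows (ties -> FOG); samples
    covered by no window are non-FOG. The resulting intervals pass through
    the same cleaning as ground-truth annotations.
    """
    n = int(round(duration_s * fs))
    votes_fog = np.zeros(n, dtype=np.int32)
    votes_all = np.zeros(n, dtype=np.int32)
    for start, pred in zip(starts, predictions):
        i0 = max(0, int(round(start * fs)))
        i1 = min(n, int(round((start + length_s) * fs)))
        votes_all[i0:i1] += 1
        if pred:
            votes_fog[i0:i1] += 1
    fog = (votes_all > 0) & (2 * votes_fog >= votes_all)

    intervals: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], fog.astype(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        intervals.append((i0 / fs, i1 / fs))
    track = clean_annotations(AnnotationTrack(intervals))
    return EpisodeSet(track=track, source=EpisodeSource.PREDICTION)


def derive_outcomes(episodes: EpisodeSet | AnnotationTrack, duration_s: float) -> DerivedOutcomes:
    """Percent time frozen, total frozen time (s), and episode count."""
    if duration_s <= 0:
        raise ValueError("trial duration must be positive")
    track = episodes.track if isinstance(episodes, EpisodeSet) else episodes
    total = track.total_duration
    return DerivedOutcomes(
        percent_time_frozen=100.0 * total / duration_s,
        total_time_frozen=total,
        n_episodes=len(track),
    )


def window_metrics(
    predicted: Sequence[bool],
    truth: Sequence[bool],
    scores: Sequence[float] | None = None,
) -> WindowMetrics:
    """Sensitivity/specificity/accuracy (%) with optional ROC/AUC.

    With no FOG windows in the truth, sensitivity is 100% by convention
    (and symmetrically specificity is 100% with no non-FOG windows).
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label sequences differ in length")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    tn = int(np.sum(~predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 100.0
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else 100.0
    acc = 100.0 * (tp + tn) / max(1, len(truth))
    auc = roc_fpr = roc_tpr = None
    if scores is not None and truth.any() and not truth.all():
        from sklearn.metrics import roc_auc_score, roc_curve

        fpr, tpr, _ = roc_curve(truth.astype(int), np.asarray(scores, float))
        auc = float(roc_auc_score(truth.astype(int), np.asarray(scores, float)))
        roc_fpr, roc_tpr = fpr, tpr
    return WindowMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                         specificity=spec, accuracy=acc, auc=auc,
                         roc_fpr=roc_fpr, roc_tpr=roc_tpr)


def freezing_index_detector(
    trial,
    window_set,
    threshold: float = 2.5,
) -> np.ndarray:
    """Threshold detector: FOG iff max-over-legs AP-acceleration FI > 2.5."""
    from .features import freezing_index
    from .signal_model import Site

    fs = trial.fs
    left = trial[Site.LEFT_ANKLE].axis("accel", "AP")
    right = trial[Site.RIGHT_ANKLE].axis("accel", "AP")
    preds = []
    for w in window_set.windows:
        i0 = int(round(w.start_s * fs))
        i1 = i0 + int(round(w.length_s * fs))
        preds.append(freezing_index(left[i0:i1], right[i0:i1], fs) > threshold)
    return np.asarray(preds, dtype=bool)
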