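"""Three-stage feature selection and the final-model commonness ranking.

Per training fold the pipeline (1) screens features with per-feature Welch
t-tests between FOG and non-FOG windows, Bonferroni-corrected at the size of
the full 86-feature manifest, (2) ranks the survivors with the greedy
minimum-redundancy-maximum-relevance (MRMR) algorithm in its MID
(mutual-information difference) form, and (3) picks the feature count whose
prefix of the ranking minimizes the subject-wise inner cross-validated
misclassification error (ties go to the smaller count). The final model's
ranking orders features by how often the per-fold selections chose them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import GroupKFold

logger = logging.getLogger(__name__)

BONFERRONI_FAMILY = 86
ALPHA = 0.05
MRMR_BINS = 10
DEFAULT_MAX_K = 20
INNER_FOLDS = 5


@dataclass
class SelectionResult:
    """Outcome of one fold's feature-selection run."""

    screened_ids: list[str]
    mrmr_ranking: list[str]
    error_curve: dict[int, float]
    chosen_k: int
    chosen_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chosen_ids:
            self.chosen_ids = self.mrmr_ranking[: self.chosen_k]


def screen_ttest(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = ALPHA,
    family: int = BONFERRONI_FAMILY,
) -> list[str]:
    """Welch t-test per feature; retain ids with p <= alpha/family.

    The Bonferroni denominator is fixed at the full manifest size. Features
    with undefined t statistics (e.g. constant in both classes) are excluded.
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("screening requires windows from both classes")
    a = X.loc[y].to_numpy(float)
    b = X.loc[~y].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sp_stats.ttest_ind(a, b, axis=0, equal_var=False)
    thresh = alpha / family
    keep = np.isfinite(p) & (p <= thresh)
    return [c for c, k in zip(X.columns, keep) if k]


def _discretize(x: np.ndarray, bins: int = MRMR_BINS) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` codes.

    Features with few distinct values (e.g. already-discrete ones) keep
    their own value codes; quantile binning would collapse them.
    """
    s = pd.Series(x)
    if s.nunique() <= bins:
        return pd.factorize(s, sort=True)[0]
    codes = pd.qcut(s, q=bins, labels=False, duplicates="drop")
    return np.nan_to_num(codes.to_numpy(float), nan=0.0).astype(int)


def mrmr_rank(X: pd.DataFrame, y: np.ndarray, ids: Sequence[str] | None = None) -> list[str]:
    """Greedy MRMR (MID scheme) ranking of the given feature ids.

    Relevance and redundancy are mutual information on equal-frequency
    10-bin discretizations; each step adds the feature maximizing
    ``I(f; y) - mean I(f; s) over selected s``. Ties resolve to the earlier
    column, making the trace deterministic.
    """
    ids = list(ids) if ids is not None else list(X.columns)
    if not ids:
        return []
    y = np.asarray(y, dtype=int)
    disc = {f: _discretize(X[f].to_numpy(float)) for f in ids}
    relevance = {f: mutual_info_score(disc[f], y) for f in ids}

    selected: list[str] = []
    remaining = list(ids)
    red_cache: dict[tuple[str, str], float] = {}

    def red(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in red_cache:
            red_cache[key] = mutual_info_score(disc[a], disc[b])
        return red_cache[key]

    while remaining:
        if not selected:
            scores = [relevance[f] for f in remaining]
        else:
            scores = [
                relevance[f] - np.mean([red(f, s) for s in selected]) for f in remaining
            ]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


def mrmr_objective(
    f: str,
    selected: Sequence[str],
    X: pd.DataFrame,
    y: np.ndarray,
    bins: int = MRMR_BINS,
) -> float:
    """The MID objective for one candidate given the already-selected set.

    Exposed separately so small instances can be checked by exhaustive
    evaluation of the greedy trace.
    """
    y = np.asarray(y, dtype=int)
    df = _discretize(X[f].to_numpy(float), bins)
    rel = mutual_info_score(df, y)
    if not selected:
        return rel
    reds = [mutual_info_score(df, _discretize(X[s].to_numpy(float), bins)) for s in selected]
    return rel - float(np.mean(reds))


def choose_count(
    ranking: Sequence[str],
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    trainer: Callable[[pd.DataFrame, np.ndarray], object],
    n_folds: int = INNER_FOLDS,
    max_k: int | None = DEFAULT_MAX_K,
    screened_ids: Sequence[str] | None = None,
) -> SelectionResult:
    """Pick the ranking prefix length minimizing inner-CV misclassification.

    Folds are subject-wise (GroupKFold) so the error estimate is
    patient-independent. ``trainer(X, y)`` must return an object with a
    ``predict(X)`` method. The search is capped at ``max_k`` features
    (None = full ranking).
    """
    ranking = list(ranking)
    if not ranking:
        raise ValueError("ranking must be non-empty")
    subjects = np.asarray(subjects)
    y = np.asarray(y, dtype=bool)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 inner subjects for subject-wise folds")
    n_splits = min(n_folds, len(uniq))
    gkf = GroupKFold(n_splits=n_splits)
    splits = list(gkf.split(X, y, groups=subjects))

    kmax = len(ranking) if max_k is None else min(max_k, len(ranking))
    error_curve: dict[int, float] = {}
    for k in range(1, kmax + 1):
        cols = ranking[:k]
        errs = []
        for tr, te in splits:
            ytr = y[tr]
            if ytr.all() or not ytr.any():
                continue  # degenerate inner fold: skip
            model = trainer(X.iloc[tr][cols], ytr)
            pred = np.asarray(model.predict(X.iloc[te][cols]), dtype=bool)
            errs.append(float(np.mean(pred != y[te])))
        error_curve[k] = float(np.mean(errs)) if errs else 1.0
    chosen_k = min(error_curve, key=lambda k: (error_curve[k], k))
    return SelectionResult(
        screened_ids=list(screened_ids) if screened_ids is not None else ranking,
        mrmr_ranking=ranking,
        error_curve=error_curve,
        chosen_k=chosen_k,
    )


def commonness_rank(fold_results: Sequence[SelectionResult]) -> list[str]:
    """Order features by how often the folds' selections chose them.

    Ties break by mean MRMR rank across the folds that ranked the feature
    (lower is better), then lexicographically by id.
    """
    if not fold_results:
        raise ValueError("need at least one fold result")
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for res in fold_results:
        for fid in res.chosen_ids:
            freq[fid] = freq.get(fid, 0) + 1
        for pos, fid in enumerate(res.mrmr_ranking):
            ranks.setdefault(fid, []).append(pos + 1)
    return sorted(
        freq,
        key=lambda f: (-freq[f], float(np.mean(ranks.get(f, [np.inf]))), f),
    )
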