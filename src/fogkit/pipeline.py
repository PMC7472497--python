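"""End-to-end experiment orchestration.

Runs simulate -> filter -> window -> featurize -> LOPO -> final model ->
detect -> evaluate as one reproducible experiment, plus the two comparator
methods (freezing-index threshold detector and the Samà back-sensor feature
set with the same SVM), and the paired per-subject method comparison.

All randomness fans out from one root seed via named substreams, so the
simulation, the subject split and the classifier are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import classifier as clf
from .classifier import LopoConfig, LopoReport, TrainedModel
from .episodes_metrics import (
    WindowMetrics,
    derive_outcomes,
    freezing_index_detector,
    window_metrics,
    windows_to_episodes,
)
from .features import (
    MANIFEST,
    compute_features,
    compute_sama_features,
    extract_window,
    fit_sama_pca,
    sama_pca_band_values,
)
from .preprocess import clean_annotations, lowpass, make_windows
from .selection import SelectionResult
from .signal_model import Site
from .synthetic import Cohort, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_META_COLS = ["subject", "trial", "start_s", "label"]


@dataclass
class ExperimentConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    test_fraction: float = 0.2      # fraction of subjects held out as test set
    feature_set: str = "full"       # full | sama | freezing-index-only
    lopo: LopoConfig = field(default_factory=LopoConfig)
    run_comparators: bool = True
    seed: int = 0

    def substream(self, name: str) -> np.random.Generator:
        # stable across processes (unlike hash()) so reruns are identical
        import zlib

        h = zlib.crc32(name.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed % (2**31), h]))


@dataclass
class MethodReport:
    """Per-subject and pooled window metrics for one detection method."""

    name: str
    per_subject: dict[str, WindowMetrics]
    pooled: WindowMetrics

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(m, attr) for m in self.per_subject.values()]))


@dataclass
class OutcomeRow:
    subject: str
    trial: str
    truth_percent_tf: float
    pred_percent_tf: float
    truth_episodes: int
    pred_episodes: int
    truth_total_s: float
    pred_total_s: float


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    train_subjects: list[str]
    test_subjects: list[str]
    lopo: LopoReport | None
    final_model: TrainedModel | None
    final_selection: SelectionResult | None
    test_metrics: WindowMetrics | None
    outcomes: list[OutcomeRow]
    spearman_percent_tf: float | None
    methods: dict[str, MethodReport]
    #: featurized windows, kept for downstream analyses (not serialized)
    prep: "PreparedCohort | None" = None

    def to_json(self) -> dict:
        def wm(m: WindowMetrics | None) -> dict | None:
            if m is None:
                return None
            return {
                "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "accuracy": m.accuracy, "auc": m.auc,
            }

        d: dict = {
            "train_subjects": self.train_subjects,
            "test_subjects": self.test_subjects,
            "feature_set": self.config.feature_set,
            "seed": self.config.seed,
            "test_metrics": wm(self.test_metrics),
            "spearman_percent_time_frozen": self.spearman_percent_tf,
            "outcomes": [vars(r) for r in self.outcomes],
            "methods": {
                name: {
                    "per_subject": {s: wm(m) for s, m in rep.per_subject.items()},
                    "pooled": wm(rep.pooled),
                }
                for name, rep in self.methods.items()
            },
        }
        if self.lopo is not None:
            d["lopo"] = self.lopo.mean_metrics() | {
                "mean_roc_auc": self.lopo.mean_roc_auc(),
                "oop": list(self.lopo.optimal_operating_point()),
                "n_folds": len(self.lopo.folds),
            }
        if self.final_selection is not None:
            d["final_features"] = self.final_selection.chosen_ids
        return d

    def save(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(json.dumps(self.to_json(), indent=2))
        return p


# --------------------------------------------------------------------------
# Featurization


@dataclass
class PreparedCohort:
    """Filtered trials, cleaned annotations and labeled windows, featurized."""

    train_df: pd.DataFrame      # train-role windows (training subjects)
    eval_df: pd.DataFrame       # test-role windows (all subjects)
    trials: dict[str, object]   # trial_key -> (filtered trial, cleaned track, test WindowSet)
    feature_ids: list[str]

    def rows(self, df: pd.DataFrame, subjects: Sequence[str]) -> pd.DataFrame:
        return df[df["subject"].isin(list(subjects))]

    def Xy(self, df: pd.DataFrame):
        return df[self.feature_ids], df["label"].to_numpy(bool), df["subject"].to_numpy()


def prepare_cohort(cohort: Cohort, train_subjects: Sequence[str]) -> PreparedCohort:
    """Filter, clean, window and featurize a cohort with the full feature set."""
    train_rows: list[dict] = []
    eval_rows: list[dict] = []
    trials: dict[str, object] = {}
    train_set = set(train_subjects)
    for subj in cohort.subjects:
        for j, st in enumerate(cohort.trials[subj]):
            key = f"{subj}/t{j}"
            filt = lowpass(st.trial)
            clean = clean_annotations(st.annotations)
            ws_test = make_windows(st.trial, clean, "test")
            trials[key] = (filt, clean, ws_test)
            for w in ws_test.windows:
                row = compute_features(extract_window(filt, w.start_s), filt.fs)
                row.update(subject=subj, trial=key, start_s=w.start_s, label=w.label)
                eval_rows.append(row)
            if subj in train_set:
                ws_train = make_windows(st.trial, clean, "train")
                for w in ws_train.windows:
                    row = compute_features(extract_window(filt, w.start_s), filt.fs)
                    row.update(subject=subj, trial=key, start_s=w.start_s, label=w.label)
                    train_rows.append(row)
    feature_ids = MANIFEST.ids
    cols = _META_COLS[:3] + ["label"] + feature_ids
    train_df = pd.DataFrame(train_rows)[cols] if train_rows else pd.DataFrame(columns=cols)
    eval_df = pd.DataFrame(eval_rows)[cols]
    return PreparedCohort(train_df=train_df, eval_df=eval_df, trials=trials,
                          feature_ids=feature_ids)


def sama_featurize(prep: PreparedCohort, cohort: Cohort, train_subjects: Sequence[str]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samà back-accel features for train-role and test-role windows.

    The spectral PCA basis is fit globally on the training-role windows.
    """
    def back_block(key: str, start: float) -> np.ndarray:
        filt, _, _ = prep.trials[key]
        return extract_window(filt, start)[Site.LOWER_BACK]["accel"]

    spectra = np.vstack([
        sama_pca_band_values(back_block(r.trial, r.start_s))
        for r in prep.train_df.itertuples()
    ])
    pca = fit_sama_pca(spectra)

    def feats(df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for r in df.itertuples():
            row = compute_sama_features(back_block(r.trial, r.start_s), pca=pca)
            row.update(subject=r.subject, trial=r.trial, start_s=r.start_s, label=r.label)
            rows.append(row)
        return pd.DataFrame(rows)

    return feats(prep.train_df), feats(prep.eval_df)


# --------------------------------------------------------------------------
# Experiment


def split_subjects(subjects: Sequence[str], test_fraction: float,
                   rng: np.random.Generator) -> tuple[list[str], list[str]]:
    subjects = sorted(subjects)
    n_test = max(1, int(round(test_fraction * len(subjects))))
    test = sorted(rng.choice(subjects, size=n_test, replace=False).tolist())
    train = [s for s in subjects if s not in set(test)]
    return train, test


def _per_subject_metrics(pred: np.ndarray, scores: np.ndarray | None,
                         df: pd.DataFrame) -> dict[str, WindowMetrics]:
    out = {}
    for subj in sorted(df["subject"].unique()):
        m = (df["subject"] == subj).to_numpy()
        s = scores[m] if scores is not None else None
        out[subj] = window_metrics(pred[m], df["label"].to_numpy(bool)[m], s)
    return out


def _outcome_rows(prep: PreparedCohort, df: pd.DataFrame, pred: np.ndarray
                  ) -> list[OutcomeRow]:
    rows = []
    for key in sorted(df["trial"].unique()):
        m = (df["trial"] == key).to_numpy()
        sub = df[m]
        filt, clean, ws_test = prep.trials[key]
        dur = filt.duration_s
        ep_pred = windows_to_episodes(sub["start_s"].to_numpy(), pred[m], dur, filt.fs)
        out_pred = derive_outcomes(ep_pred, dur)
        out_truth = derive_outcomes(clean, dur)
        rows.append(OutcomeRow(
            subject=str(sub["subject"].iloc[0]), trial=key,
            truth_percent_tf=out_truth.percent_time_frozen,
            pred_percent_tf=out_pred.percent_time_frozen,
            truth_episodes=out_truth.n_episodes, pred_episodes=out_pred.n_episodes,
            truth_total_s=out_truth.total_time_frozen,
            pred_total_s=out_pred.total_time_frozen,
        ))
    return rows


def run_experiment(config: ExperimentConfig, cohort: Cohort | None = None
                   ) -> ExperimentReport:
    """Run the full experiment; deterministic given the config seed."""
    if cohort is None:
        sim_cfg = config.sim
        sim_seed = int(config.substream("simulate").integers(2**31))
        from dataclasses import replace as dc_replace
        cohort = simulate_cohort(dc_replace(sim_cfg, seed=sim_seed))
    train_subj, test_subj = split_subjects(
        cohort.subjects, config.test_fraction, config.substream("split")
    )
    logger.info("split: %d training / %d test subjects", len(train_subj), len(test_subj))
    prep = prepare_cohort(cohort, train_subj)
    logger.info("windows: %d train-role, %d test-role; %d features",
                len(prep.train_df), len(prep.eval_df), len(prep.feature_ids))

    eval_train = prep.rows(prep.eval_df, train_subj)
    eval_test = prep.rows(prep.eval_df, test_subj)

    methods: dict[str, MethodReport] = {}

    # --- freezing-index threshold detector (training cohort, per subject)
    if config.run_comparators or config.feature_set == "freezing-index-only":
        fi_pred = []
        for key in sorted(eval_train["trial"].unique()):
            filt, _, ws_test = prep.trials[key]
            fi_pred.append(freezing_index_detector(filt, ws_test))
        # eval rows were appended trial-by-trial; align per-trial predictions
        # back to eval_train's row order
        fi_map = dict(zip(sorted(eval_train["trial"].unique()), fi_pred))
        pred = np.concatenate([
            fi_map[key] for key in eval_train["trial"].drop_duplicates()
        ])
        methods["freezing_index"] = MethodReport(
            name="freezing_index",
            per_subject=_per_subject_metrics(pred, None, eval_train),
            pooled=window_metrics(pred, eval_train["label"].to_numpy(bool)),
        )

    if config.feature_set == "freezing-index-only":
        return ExperimentReport(
            config=config, train_subjects=train_subj, test_subjects=test_subj,
            lopo=None, final_model=None, final_selection=None, test_metrics=None,
            outcomes=[], spearman_percent_tf=None, methods=methods, prep=prep,
        )

    # --- proposed pipeline: LOPO with per-fold selection
    Xtr, ytr, str_ = prep.Xy(prep.rows(prep.train_df, train_subj))
    Xev, yev, sev = prep.Xy(eval_train)
    lopo = clf.lopo_validate(Xtr, ytr, str_, Xev, yev, sev, config.lopo)
    methods["proposed"] = MethodReport(
        name="proposed",
        per_subject={f.subject: f.metrics for f in lopo.folds},
        pooled=window_metrics(np.zeros(0, bool), np.zeros(0, bool)),  # filled below
    )

    # --- final model on all training subjects; evaluate on the test set
    final_model, final_sel = clf.build_final_model(Xtr, ytr, str_, lopo, config.lopo)
    Xte = eval_test[prep.feature_ids]
    scores_te = final_model.decision_scores(Xte)
    pred_te = scores_te > 0
    test_metrics = window_metrics(pred_te, eval_test["label"].to_numpy(bool), scores_te)

    outcomes = _outcome_rows(prep, eval_test, pred_te)
    truth_tf = np.array([r.truth_percent_tf for r in outcomes])
    pred_tf = np.array([r.pred_percent_tf for r in outcomes])
    spearman = None
    if len(outcomes) >= 3 and np.std(truth_tf) > 0 and np.std(pred_tf) > 0:
        spearman = float(sp_stats.spearmanr(truth_tf, pred_tf).statistic)

    # --- Samà comparator: same SVM, back-sensor feature set, no selection
    if config.run_comparators and config.feature_set in ("full", "sama"):
        sama_train, sama_eval = sama_featurize(prep, cohort, train_subj)
        sama_ids = [c for c in sama_train.columns if c.startswith("sama_")]
        sama_eval_train = sama_eval[sama_eval["subject"].isin(train_subj)]
        sama_cfg = LopoConfig(select_features=False, seed=config.lopo.seed)
        sama_lopo = clf.lopo_validate(
            sama_train[sama_ids], sama_train["label"].to_numpy(bool),
            sama_train["subject"].to_numpy(),
            sama_eval_train[sama_ids], sama_eval_train["label"].to_numpy(bool),
            sama_eval_train["subject"].to_numpy(), sama_cfg,
        )
        methods["sama"] = MethodReport(
            name="sama",
            per_subject={f.subject: f.metrics for f in sama_lopo.folds},
            pooled=window_metrics(np.zeros(0, bool), np.zeros(0, bool)),
        )

    # pooled proposed metrics across LOPO folds from the fold confusion counts
    prop = methods["proposed"].per_subject
    tp = sum(m.tp for m in prop.values()); fp = sum(m.fp for m in prop.values())
    tn = sum(m.tn for m in prop.values()); fn = sum(m.fn for m in prop.values())
    methods["proposed"].pooled = WindowMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else 100.0,
        specificity=100.0 * tn / (tn + fp) if tn + fp else 100.0,
        accuracy=100.0 * (tp + tn) / max(1, tp + tn + fp + fn),
    )
    if "sama" in methods:
        sm = methods["sama"].per_subject
        tp = sum(m.tp for m in sm.values()); fp = sum(m.fp for m in sm.values())
        tn = sum(m.tn for m in sm.values()); fn = sum(m.fn for m in sm.values())
        methods["sama"].pooled = WindowMetrics(
            tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=100.0 * tp / (tp + fn) if tp + fn else 100.0,
            specificity=100.0 * tn / (tn + fp) if tn + fp else 100.0,
            accuracy=100.0 * (tp + tn) / max(1, tp + tn + fp + fn),
        )

    return ExperimentReport(
        config=config, train_subjects=train_subj, test_subjects=test_subj,
        lopo=lopo, final_model=final_model, final_selection=final_sel,
        test_metrics=test_metrics, outcomes=outcomes,
        spearman_percent_tf=spearman, methods=methods, prep=prep,
    )


def compare_methods(methods: dict[str, MethodReport]) -> pd.DataFrame:
    """Paired per-subject comparison with Wilcoxon signed-rank p-values.

    Returns one row per (method pair, metric) with mean difference and the
    two-sided exact-when-possible Wilcoxon p-value. Identical reports give
    difference 0 and p = 1.
    """
    names = sorted(methods)
    subj_sets = [set(methods[n].per_subject) for n in names]
    common = set.intersection(*subj_sets)
    if any(s != common for s in subj_sets):
        raise ValueError("method reports cover different subjects")
    subjects = sorted(common)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for metric in ("sensitivity", "specificity", "accuracy"):
                da = np.array([getattr(methods[a].per_subject[s], metric) for s in subjects])
                db = np.array([getattr(methods[b].per_subject[s], metric) for s in subjects])
                diff = da - db
                if np.allclose(diff, 0.0):
                    p = 1.0
                else:
                    try:
                        p = float(sp_stats.wilcoxon(da, db, mode="exact").pvalue)
                    except ValueError:
                        p = float(sp_stats.wilcoxon(da, db).pvalue)
                rows.append({"method_a": a, "method_b": b, "metric": metric,
                             "mean_diff": float(np.mean(diff)), "wilcoxon_p": p})
    return pd.DataFrame(rows)
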