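"""Low-pass filtering, annotation cleaning and window extraction.

The detection pipeline operates on 3-second windows. Training windows are
cut with asymmetric overlap — 80% inside freezing regions (0.6 s step) and
50% elsewhere (1.5 s step) — to enrich the minority FOG class; test windows
use a uniform 1.5 s step. A window is labeled FOG when at least 1.5 s of it
is covered by annotated freezing. Ground-truth annotation tracks are first
cleaned by merging episodes separated by less than one second and then
dropping episodes shorter than one second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .signal_model import AnnotationTrack, SensorRecording, TrialRecording

logger = logging.getLogger(__name__)

WINDOW_LENGTH_S = 3.0
TEST_STEP_S = 1.5          # 50% overlap
TRAIN_FOG_STEP_S = 0.6     # 80% overlap inside FOG regions
TRAIN_NONFOG_STEP_S = 1.5  # 50% overlap elsewhere
FOG_OVERLAP_THRESHOLD_S = 1.5

LOWPASS_CUTOFF_HZ = 15.0
LOWPASS_ORDER = 2

MERGE_GAP_S = 1.0
MIN_EPISODE_S = 1.0


def lowpass(trial: TrialRecording, cutoff_hz: float = LOWPASS_CUTOFF_HZ) -> TrialRecording:
    """Zero-phase second-order Butterworth low-pass filter of every channel.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth magnitude and no phase distortion
    shifts episode boundaries.
    """
    fs = trial.fs
    if fs <= 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {cutoff_hz} Hz cutoff"
        )
    sos = sp_signal.butter(LOWPASS_ORDER, cutoff_hz, btype="low", fs=fs, output="sos")
    recs = {
        site: SensorRecording(
            site=site,
            accel=sp_signal.sosfiltfilt(sos, rec.accel, axis=1),
            gyro=sp_signal.sosfiltfilt(sos, rec.gyro, axis=1),
            fs=fs,
        )
        for site, rec in trial.recordings.items()
    }
    return TrialRecording(
        recordings=recs,
        subject_id=trial.subject_id,
        med_state=trial.med_state,
        difficulty=trial.difficulty,
    )


def clean_annotations(
    track: AnnotationTrack,
    merge_gap_s: float = MERGE_GAP_S,
    min_episode_s: float = MIN_EPISODE_S,
) -> AnnotationTrack:
    """Merge episodes separated by < ``merge_gap_s``, then drop episodes
    shorter than ``min_episode_s``.

    Merging runs first so that fragmented real episodes are preserved: two
    sub-second fragments less than a second apart merge into one episode
    that may then survive the duration cut. The operation is idempotent.
    """
    merged: list[list[float]] = []
    for s, e in track.intervals:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_episode_s]
    return AnnotationTrack(kept)


@dataclass(frozen=True)
class Window:
    """One 3-second analysis window of a trial."""

    start_s: float
    label: bool                 # True = FOG
    fog_overlap_s: float
    length_s: float = WINDOW_LENGTH_S

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s


@dataclass
class WindowSet:
    """Labeled windows cut from one trial, for one role (train or test)."""

    windows: list[Window]
    role: str                   # 'train' | 'test'
    trial_duration_s: float
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError("role must be 'train' or 'test'")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def starts(self) -> np.ndarray:
        return np.array([w.start_s for w in self.windows])

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=bool)


def _grid_starts(duration_s: float, step_s: float, length_s: float) -> np.ndarray:
    """Window starts i*step with the full window inside the trial."""
    n = int(np.floor((duration_s - length_s) / step_s + 1e-9)) + 1
    if n <= 0:
        return np.array([])
    return np.arange(n) * step_s


def make_windows(
    trial: TrialRecording | float,
    track: AnnotationTrack,
    role: str,
    length_s: float = WINDOW_LENGTH_S,
) -> WindowSet:
    """Cut and label fixed-length windows from a trial.

    ``trial`` may be a TrialRecording or a bare duration in seconds. Both
    training grids are anchored at t=0; a training start is kept from the
    0.6 s grid when its window is FOG-labeled and from the 1.5 s grid when
    non-FOG, duplicates collapsed. Windows extending past the trial end are
    discarded.
    """
    if isinstance(trial, TrialRecording):
        duration = trial.duration_s
        subject_id = trial.subject_id
    else:
        duration = float(trial)
        subject_id = ""
    if duration < length_s:
        logger.warning("trial of %.2f s is shorter than one window; empty set", duration)
        return WindowSet([], role=role, trial_duration_s=duration, subject_id=subject_id)

    def _label(start: float) -> tuple[bool, float]:
        ov = track.overlap_with(start, start + length_s)
        return ov >= FOG_OVERLAP_THRESHOLD_S - 1e-9, ov

    windows: list[Window] = []
    if role == "test":
        for start in _grid_starts(duration, TEST_STEP_S, length_s):
            lab, ov = _label(start)
            windows.append(Window(start_s=float(start), label=lab, fog_overlap_s=ov))
    elif role == "train":
        starts: dict[float, Window] = {}
        for start in _grid_starts(duration, TRAIN_FOG_STEP_S, length_s):
            lab, ov = _label(start)
            if lab:
                starts[round(float(start), 9)] = Window(float(start), lab, ov)
        for start in _grid_starts(duration, TRAIN_NONFOG_STEP_S, length_s):
            lab, ov = _label(start)
            if not lab:
                starts[round(float(start), 9)] = Window(float(start), lab, ov)
        windows = [starts[k] for k in sorted(starts)]
    else:
        raise ValueError("role must be 'train' or 'test'")
    return WindowSet(windows, role=role, trial_duration_s=duration, subject_id=subject_id)
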