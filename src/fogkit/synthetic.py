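"""Synthetic tri-site IMU cohorts with scheduled FOG episodes.

The generator emulates the spectral signature that separates freezing from
gait: walking puts its dominant energy in the 0.5-3 Hz walk band (cadence
fundamental plus a weaker first harmonic) with trunk movement comparable to
leg movement; trembling freezing drives the legs at a 3-8 Hz tremor
frequency while trunk movement collapses (the dissociation motivating the
legs-to-back RMS ratio features); akinetic freezing is near-total movement
arrest; quiet standing shows only low-frequency postural sway. Episodes are
scheduled with Poisson counts and truncated log-normal durations, akinetic
with a configured probability, and the annotation track covers exactly the
trembling and akinetic samples. Gravity appears as a constant 9.81 m/s^2
offset on the vertical accelerometer axis; white sensor noise is added
everywhere and 0.2 s raised-cosine cross-fades smooth state changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_model import (
    AnnotationTrack,
    MedState,
    SensorRecording,
    Site,
    TrialRecording,
    write_annotations,
    write_trial,
)

logger = logging.getLogger(__name__)

GRAVITY = 9.81

STATE_WALK = 0
STATE_TREMBLE = 1
STATE_AKINETIC = 2
STATE_STAND = 3
STATE_NAMES = {0: "walk", 1: "tremble", 2: "akinetic", 3: "stand"}


@dataclass
class AmplitudeSet:
    """Per-state oscillation amplitudes (accel m/s^2, gyro deg/s)."""

    walk_leg_accel: float = 1.6
    walk_leg_gyro: float = 60.0
    walk_back_accel: float = 1.2
    walk_back_gyro: float = 35.0
    harmonic_ratio: float = 0.3        # first harmonic relative amplitude
    tremble_leg_accel: float = 1.4
    tremble_leg_gyro: float = 50.0
    back_dissociation: float = 0.08    # trunk amplitude factor during trembling
    sway_accel: float = 0.06           # quiet-standing postural sway
    sway_gyro: float = 2.0
    sway_hz: float = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a FOG-provoking test cohort at desk scale: 25 subjects
    with two 40 s trials each (about half an hour of signal), cadence near 1.8 Hz
    inside the 0.5-3 Hz walk band, subject tremor frequencies drawn in the
    3-8 Hz freeze band, and 1-11 freezing episodes per trial with log-normal
    durations. The scheduler enforces >= 1.2 s episode durations and
    inter-episode gaps so generated ground truth is stable under the
    merge/drop annotation cleaning; ``dirty`` mode relaxes this to exercise
    the cleaner.
    """

    n_subjects: int = 25
    n_trials: int = 2
    duration_s: float = 40.0
    fs: float = 128.0
    cadence_hz: float = 1.8
    cadence_sd: float = 0.15
    tremor_range: tuple[float, float] = (3.5, 7.5)
    episode_rate: float = 3.0          # Poisson mean FOG episodes per trial
    episode_lognorm_mu: float = 1.5    # log seconds (median ~4.5 s)
    episode_lognorm_sigma: float = 0.5
    min_episode_s: float = 1.2
    min_gap_s: float = 1.2
    akinetic_fraction: float = 0.2
    stand_lead_s: float = 2.5          # quiet standing at trial start
    noise_sd_accel: float = 0.05
    noise_sd_gyro: float = 1.5
    amplitudes: AmplitudeSet = field(default_factory=AmplitudeSet)
    amp_jitter_sd: float = 0.15        # log-normal per-subject amplitude jitter
    crossfade_s: float = 0.2
    dirty: bool = False
    seed: int = 0


@dataclass
class SimulatedTrial:
    trial: TrialRecording
    annotations: AnnotationTrack
    states: np.ndarray  # per-sample state code


def _schedule_episodes(cfg: SimulationConfig, rng: np.random.Generator
                       ) -> list[tuple[float, float, bool]]:
    """Draw (start, end, akinetic?) episodes fitting inside the trial."""
    n = rng.poisson(cfg.episode_rate)
    if cfg.dirty:
        min_ep, min_gap = 0.3, 0.3
    else:
        min_ep, min_gap = cfg.min_episode_s, cfg.min_gap_s
    lo = cfg.stand_lead_s + min_gap
    hi = cfg.duration_s - min_gap
    episodes: list[tuple[float, float, bool]] = []
    for _ in range(n):
        dur = float(np.exp(rng.normal(cfg.episode_lognorm_mu, cfg.episode_lognorm_sigma)))
        dur = max(min_ep, min(dur, 20.0))
        for _attempt in range(50):
            start = float(rng.uniform(lo, hi - dur))
            ok = all(
                start >= e + min_gap or start + dur <= s - min_gap
                for s, e, _ in episodes
            )
            if ok:
                episodes.append((start, start + dur, bool(rng.random() < cfg.akinetic_fraction)))
                break
    episodes.sort()
    return episodes


def _state_sequence(cfg: SimulationConfig, episodes, n: int) -> np.ndarray:
    states = np.full(n, STATE_WALK, dtype=np.int8)
    states[: int(round(cfg.stand_lead_s * cfg.fs))] = STATE_STAND
    for s, e, akin in episodes:
        i0, i1 = int(round(s * cfg.fs)), int(round(e * cfg.fs))
        states[i0:i1] = STATE_AKINETIC if akin else STATE_TREMBLE
    return states


def _smooth_mask(mask: np.ndarray, fs: float, fade_s: float) -> np.ndarray:
    """Raised-cosine smoothing of a 0/1 state mask (normalized kernel)."""
    k = int(round(fade_s * fs))
    if k < 2:
        return mask.astype(float)
    kern = np.hanning(k)
    kern /= kern.sum()
    return np.convolve(mask.astype(float), kern, mode="same")


@dataclass
class _SubjectParams:
    cadence_hz: float
    tremor_hz: float
    amp: AmplitudeSet


def _draw_subject(cfg: SimulationConfig, rng: np.random.Generator) -> _SubjectParams:
    cadence = float(np.clip(rng.normal(cfg.cadence_hz, cfg.cadence_sd), 1.0, 2.8))
    tremor = float(rng.uniform(*cfg.tremor_range))
    j = lambda v: float(v * np.exp(rng.normal(0.0, cfg.amp_jitter_sd)))
    a = cfg.amplitudes
    amp = replace(
        a,
        walk_leg_accel=j(a.walk_leg_accel),
        walk_leg_gyro=j(a.walk_leg_gyro),
        walk_back_accel=j(a.walk_back_accel),
        walk_back_gyro=j(a.walk_back_gyro),
        tremble_leg_accel=j(a.tremble_leg_accel),
        tremble_leg_gyro=j(a.tremble_leg_gyro),
    )
    return _SubjectParams(cadence_hz=cadence, tremor_hz=tremor, amp=amp)


def _oscillation(t: np.ndarray, freq: float, amp: float, harmonic: float,
                 phase: float) -> np.ndarray:
    x = amp * np.sin(2 * np.pi * freq * t + phase)
    if harmonic > 0:
        x += amp * harmonic * np.sin(2 * np.pi * 2 * freq * t + 2 * phase)
    return x


def simulate_trial(
    cfg: SimulationConfig,
    params: _SubjectParams | None = None,
    seed: int | np.random.SeedSequence | None = None,
    subject_id: str = "S00",
    difficulty: int = 1,
) -> SimulatedTrial:
    """Generate one trial: signals, exact annotations and the state track."""
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    if params is None:
        params = _draw_subject(cfg, rng)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    episodes = _schedule_episodes(cfg, rng)
    states = _state_sequence(cfg, episodes, n)

    masks = {
        s: _smooth_mask(states == s, cfg.fs, cfg.crossfade_s)
        for s in (STATE_WALK, STATE_TREMBLE, STATE_AKINETIC, STATE_STAND)
    }
    a = params.amp
    cad, trem = params.cadence_hz, params.tremor_hz

    def site_signals(site: Site) -> tuple[np.ndarray, np.ndarray]:
        is_leg = site != Site.LOWER_BACK
        phase = {Site.LOWER_BACK: 0.0, Site.LEFT_ANKLE: 0.0, Site.RIGHT_ANKLE: np.pi}[site]
        accel = np.zeros((3, n))
        gyro = np.zeros((3, n))
        walk_acc = a.walk_leg_accel if is_leg else a.walk_back_accel
        walk_gyr = a.walk_leg_gyro if is_leg else a.walk_back_gyro
        trem_acc = a.tremble_leg_accel if is_leg else a.tremble_leg_accel * a.back_dissociation
        trem_gyr = a.tremble_leg_gyro if is_leg else a.tremble_leg_gyro * a.back_dissociation
        for i, axis_gain in enumerate((0.8, 1.0, 0.5)):  # V, AP, ML relative motion
            ph = phase + i * 0.7
            walk_wave_a = _oscillation(t, cad, walk_acc * axis_gain, a.harmonic_ratio, ph)
            walk_wave_g = _oscillation(t, cad, walk_gyr * axis_gain, a.harmonic_ratio, ph)
            trem_wave_a = _oscillation(t, trem, trem_acc * axis_gain, 0.0, ph)
            trem_wave_g = _oscillation(t, trem, trem_gyr * axis_gain, 0.0, ph)
            sway_a = _oscillation(t, a.sway_hz, a.sway_accel * axis_gain, 0.0, ph)
            sway_g = _oscillation(t, a.sway_hz, a.sway_gyro * axis_gain, 0.0, ph)
            accel[i] = (
                masks[STATE_WALK] * walk_wave_a
                + masks[STATE_TREMBLE] * trem_wave_a
                + masks[STATE_STAND] * sway_a
            )
            gyro[i] = (
                masks[STATE_WALK] * walk_wave_g
                + masks[STATE_TREMBLE] * trem_wave_g
                + masks[STATE_STAND] * sway_g
            )
        accel += rng.normal(0.0, cfg.noise_sd_accel, size=accel.shape)
        gyro += rng.normal(0.0, cfg.noise_sd_gyro, size=gyro.shape)
        accel[0] += GRAVITY  # gravity rides on the vertical axis
        return accel, gyro

    recordings = {
        site: SensorRecording(site=site, accel=acc, gyro=gyr, fs=cfg.fs)
        for site in Site
        for acc, gyr in (site_signals(site),)
    }
    trial = TrialRecording(
        recordings=recordings,
        subject_id=subject_id,
        med_state=MedState.OFF,
        difficulty=difficulty,
    )
    annotations = AnnotationTrack([(s, e) for s, e, _ in episodes])
    return SimulatedTrial(trial=trial, annotations=annotations, states=states)


@dataclass
class Cohort:
    trials: dict[str, list[SimulatedTrial]]  # subject_id -> trials

    @property
    def subjects(self) -> list[str]:
        return sorted(self.trials)

    def all_trials(self):
        for subj in self.subjects:
            for st in self.trials[subj]:
                yield subj, st


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate a cohort: per-subject gait/tremor parameters, jittered
    amplitudes, ``n_trials`` trials each (one per difficulty level)."""
    if cfg.n_subjects < 1:
        raise ValueError("need at least one subject")
    root = np.random.SeedSequence(cfg.seed)
    subj_seqs = root.spawn(cfg.n_subjects)
    cohort: dict[str, list[SimulatedTrial]] = {}
    for i, seq in enumerate(subj_seqs):
        subject_id = f"S{i:02d}"
        param_seq, *trial_seqs = seq.spawn(cfg.n_trials + 1)
        params = _draw_subject(cfg, np.random.default_rng(param_seq))
        cohort[subject_id] = [
            simulate_trial(
                cfg, params=params, seed=ts, subject_id=subject_id,
                difficulty=min(j + 1, 3),
            )
            for j, ts in enumerate(trial_seqs)
        ]
    return Cohort(trials=cohort)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every trial in the on-disk CSV/JSON dialect."""
    out = Path(out_dir)
    for subj in cohort.subjects:
        for j, st in enumerate(cohort.trials[subj]):
            d = out / subj / f"trial_{j:02d}"
            write_trial(st.trial, d)
            write_annotations(st.annotations, d / "annotations.json")
    return out
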