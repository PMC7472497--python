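"""Core data types and file I/O for tri-site inertial recordings.

A trial is one pass of the FOG-provoking test recorded by three inertial
sensors (lower back, left ankle, right ankle), each providing a tri-axial
accelerometer (m/s^2) and gyroscope (deg/s) sampled at a common rate,
with axes ordered vertical (V), anterior-posterior (AP), medio-lateral (ML).
Ground-truth freezing episodes are stored as ordered, disjoint, half-open
``[start, end)`` intervals in seconds from trial start.

On-disk dialect (plain text): one CSV per site with comment headers
``#fs=<Hz>`` and ``#units=m/s2,deg/s`` followed by columns
``t,accV,accAP,accML,gyrV,gyrAP,gyrML`` (any column order; mapped by name;
magnetometer columns are ignored), a ``meta.json`` sidecar with subject id,
medication state and difficulty level, and ``annotations.json`` holding a
JSON array of ``{"start_s": ..., "end_s": ...}`` objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXES = ("V", "AP", "ML")

#: Canonical accelerometer / gyroscope units of the file dialect.
ACCEL_UNITS = "m/s2"
GYRO_UNITS = "deg/s"


class Site(str, Enum):
    LOWER_BACK = "lower_back"
    LEFT_ANKLE = "left_ankle"
    RIGHT_ANKLE = "right_ankle"


class MedState(str, Enum):
    OFF = "OFF"
    ON = "ON"


@dataclass
class SensorRecording:
    """Tri-axial accelerometer + gyroscope stream from one body site.

    ``accel`` and ``gyro`` are ``(3, N)`` arrays with rows ordered (V, AP, ML).
    """

    site: Site
    accel: np.ndarray
    gyro: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise ValueError(
                f"{self.site.value}: accel {self.accel.shape} and gyro {self.gyro.shape} "
                "must both be (3, N)"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]

    def axis(self, channel: str, axis: str) -> np.ndarray:
        """Return one axis signal; ``channel`` is 'accel' or 'gyro'."""
        arr = {"accel": self.accel, "gyro": self.gyro}[channel]
        return arr[AXES.index(axis)]


@dataclass
class TrialRecording:
    """Synchronized three-site recording of one FOG-provoking test trial."""

    recordings: dict[Site, SensorRecording]
    subject_id: str
    med_state: MedState = MedState.OFF
    difficulty: int = 1

    def __post_init__(self) -> None:
        self.recordings = {Site(k): v for k, v in self.recordings.items()}
        self.med_state = MedState(self.med_state)
        missing = [s.value for s in Site if s not in self.recordings]
        if missing:
            raise ValueError(f"missing site recording(s): {', '.join(missing)}")
        if self.difficulty not in (1, 2, 3):
            raise ValueError("difficulty must be 1, 2 or 3")
        ref = self.recordings[Site.LOWER_BACK]
        for rec in self.recordings.values():
            if rec.fs != ref.fs:
                raise ValueError("all sites must share the sampling rate")
            if rec.n_samples != ref.n_samples:
                raise ValueError(
                    f"site {rec.site.value} has {rec.n_samples} samples, "
                    f"expected {ref.n_samples}"
                )

    @property
    def fs(self) -> float:
        return self.recordings[Site.LOWER_BACK].fs

    @property
    def n_samples(self) -> int:
        return self.recordings[Site.LOWER_BACK].n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, site: Site | str) -> SensorRecording:
        return self.recordings[Site(site)]


@dataclass
class AnnotationTrack:
    """Ordered, disjoint FOG intervals, half-open [start, end) in seconds."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = [(float(s), float(e)) for s, e in self.intervals]
        for i, (s, e) in enumerate(iv):
            if s < 0:
                raise ValueError(f"negative start at index {i}")
            if e <= s:
                raise ValueError(f"inverted interval at index {i}")
        for i in range(1, len(iv)):
            if iv[i][0] < iv[i - 1][1]:
                raise ValueError(f"overlapping intervals at index {i}")
        self.intervals = iv

    @classmethod
    def from_unsorted(cls, pairs: Iterable[tuple[float, float]]) -> "AnnotationTrack":
        return cls(sorted([(float(s), float(e)) for s, e in pairs]))

    @property
    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against(self, duration_s: float) -> None:
        for i, (_, e) in enumerate(self.intervals):
            if e > duration_s + 1e-9:
                raise ValueError(
                    f"interval {i} ends at {e} s, beyond trial duration {duration_s} s"
                )

    def overlap_with(self, start: float, end: float) -> float:
        """Total annotated time inside the half-open window [start, end)."""
        tot = 0.0
        for s, e in self.intervals:
            tot += max(0.0, min(e, end) - max(s, start))
        return tot


# --------------------------------------------------------------------------
# Feature manifest


@dataclass(frozen=True)
class FeatureSpec:
    """Definition of one per-window feature.

    ``source`` names the sensor group (back or leg-aggregated); ``leg_agg``
    is the aggregation over the two legs ('max' or 'min') for leg-sourced
    features, None otherwise.
    """

    feature_id: str
    source: str            # back | legs | legs_and_back
    channel: str           # accel | gyro | accel+gyro
    axis: str              # V | AP | ML | VAPML (tri-axial) | interleg spec
    domain: str            # time | frequency
    band: tuple[float, float] | None = None
    leg_agg: str | None = None


@dataclass
class FeatureManifest:
    entries: list[FeatureSpec]

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, ids: Sequence[str]) -> "FeatureManifest":
        by_id = {e.feature_id: e for e in self.entries}
        return FeatureManifest([by_id[i] for i in ids])

    def to_json(self) -> list[dict]:
        return [
            {
                "feature_id": e.feature_id,
                "source": e.source,
                "channel": e.channel,
                "axis": e.axis,
                "domain": e.domain,
                "band": list(e.band) if e.band else None,
                "leg_agg": e.leg_agg,
            }
            for e in self.entries
        ]


# --------------------------------------------------------------------------
# File I/O

_SITE_FILES = {s: f"{s.value}.csv" for s in Site}
_COLUMN_MAP = {f"acc{a}": ("accel", a) for a in AXES} | {f"gyr{a}": ("gyro", a) for a in AXES}


def _read_site_csv(path: Path) -> SensorRecording:
    headers: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            headers[key] = val
    if "fs" not in headers:
        raise ValueError(f"{path}: missing '#fs=' header")
    fs = float(headers["fs"])
    units = headers.get("units", f"{ACCEL_UNITS},{GYRO_UNITS}")
    if units != f"{ACCEL_UNITS},{GYRO_UNITS}":
        raise ValueError(f"{path}: unsupported units '{units}'")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    accel = np.zeros((3, len(df)))
    gyro = np.zeros((3, len(df)))
    seen: set[str] = set()
    for col in df.columns:
        if col == "t":
            continue
        if col.startswith("mag"):
            logger.info("%s: ignoring magnetometer column %s", path.name, col)
            continue
        if col not in _COLUMN_MAP:
            raise ValueError(f"{path}: unknown axis label '{col}'")
        channel, axis = _COLUMN_MAP[col]
        (accel if channel == "accel" else gyro)[AXES.index(axis)] = df[col].to_numpy(float)
        seen.add(col)
    missing = sorted(set(_COLUMN_MAP) - seen)
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    site = Site(path.stem)
    return SensorRecording(site=site, accel=accel, gyro=gyro, fs=fs)


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial directory containing the three site CSVs and meta.json."""
    d = Path(path)
    if not d.is_dir():
        raise FileNotFoundError(f"trial path {d} is not a directory")
    recs: dict[Site, SensorRecording] = {}
    for site, fname in _SITE_FILES.items():
        f = d / fname
        if not f.exists():
            raise FileNotFoundError(f"missing site file for '{site.value}': {f}")
        recs[site] = _read_site_csv(f)
    meta_path = d / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrialRecording(
        recordings=recs,
        subject_id=str(meta.get("subject_id", d.name)),
        med_state=MedState(meta.get("med_state", "OFF")),
        difficulty=int(meta.get("difficulty", 1)),
    )


def write_trial(trial: TrialRecording, path: str | Path, float_fmt: str = "%.17g") -> Path:
    # %.17g round-trips IEEE doubles exactly, so write->read is the identity.
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.fs
    for site, rec in trial.recordings.items():
        cols = {"t": t}
        for a in AXES:
            cols[f"acc{a}"] = rec.accel[AXES.index(a)]
        for a in AXES:
            cols[f"gyr{a}"] = rec.gyro[AXES.index(a)]
        f = d / _SITE_FILES[site]
        with open(f, "w") as fh:
            fh.write(f"#fs={trial.fs:g}\n#units={ACCEL_UNITS},{GYRO_UNITS}\n")
            pd.DataFrame(cols).to_csv(fh, index=False, float_format=float_fmt)
    (d / "meta.json").write_text(
        json.dumps(
            {
                "subject_id": trial.subject_id,
                "med_state": trial.med_state.value,
                "difficulty": trial.difficulty,
            },
            indent=2,
        )
    )
    return d


def read_annotations(path: str | Path, trial: TrialRecording | None = None) -> AnnotationTrack:
    """Read a JSON array of {"start_s", "end_s"} objects into a sorted track."""
    raw = json.loads(Path(path).read_text())
    track = AnnotationTrack.from_unsorted((item["start_s"], item["end_s"]) for item in raw)
    if trial is not None:
        track.validate_against(trial.duration_s)
    return track


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    p = Path(path)
    p.write_text(
        json.dumps([{"start_s": s, "end_s": e} for s, e in track.intervals], indent=2)
    )
    return p
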