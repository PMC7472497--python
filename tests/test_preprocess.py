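"""Filtering, annotation cleaning and windowing, checked against
per-sample brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fogkit.preprocess import (
    FOG_OVERLAP_THRESHOLD_S,
    TEST_STEP_S,
    TRAIN_FOG_STEP_S,
    clean_annotations,
    lowpass,
    make_windows,
)
from fogkit.signal_model import AnnotationTrack, Site

from conftest import make_trial

FS = 128.0


def sine_trial(freq, duration_s=10.0, amp=1.0):
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    wave = amp * np.sin(2 * np.pi * freq * t)
    block = np.tile(wave, (3, 1))
    return make_trial(duration_s, fill=lambda site, ch: block.copy())


def steady_amplitude(x):
    """Peak amplitude away from filter edge effects."""
    n = len(x)
    return np.max(np.abs(x[n // 4: 3 * n // 4]))


class TestLowpass:
    def test_dc_unity_gain(self):
        trial = make_trial(2.0, fill=lambda s, c: np.full((3, 256), 5.0))
        out = lowpass(trial)
        np.testing.assert_allclose(out[Site.LOWER_BACK].accel, 5.0, atol=1e-9)

    def test_5hz_attenuation_matches_squared_butterworth(self):
        # zero-phase 2nd-order Butterworth: |H|^2 = 1/(1+(f/15)^4)
        out = lowpass(sine_trial(5.0))
        expected = 1.0 / (1.0 + (5.0 / 15.0) ** 4)
        amp = steady_amplitude(out[Site.LEFT_ANKLE].accel[1])
        assert amp == pytest.approx(expected, abs=5e-3)

    def test_30hz_strongly_attenuated(self):
        out = lowpass(sine_trial(30.0))
        amp = steady_amplitude(out[Site.LEFT_ANKLE].accel[1])
        assert amp <= 0.10
        # forward-backward pass of the digital design: |H(30 Hz)|^2
        from scipy import signal as sp

        sos = sp.butter(2, 15.0, btype="low", fs=FS, output="sos")
        _, h = sp.sosfreqz(sos, worN=[30.0], fs=FS)
        assert amp == pytest.approx(np.abs(h[0]) ** 2, abs=5e-3)

    def test_length_preserved(self, small_trial):
        out = lowpass(small_trial)
        assert out.n_samples == small_trial.n_samples

    def test_low_sampling_rate_fatal(self):
        trial = make_trial(4.0, fs=30.0)
        with pytest.raises(ValueError, match="sampling rate"):
            lowpass(trial)


class TestCleanAnnotations:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 2), (2.5, 4)], [(0, 4)]),          # 0.5 s gap merges
            ([(0, 0.8)], []),                         # short episode dropped
            ([(0, 0.6), (1.2, 1.9)], [(0, 1.9)]),     # merge-first rescues fragments
            ([], []),
            ([(0, 1.0)], [(0, 1.0)]),                 # exactly 1 s survives
            ([(0, 2), (3.0, 5)], [(0, 2), (3, 5)]),   # gap of exactly 1 s kept apart
        ],
    )
    def test_examples(self, raw, expected):
        out = clean_annotations(AnnotationTrack(raw))
        assert out.intervals == [(float(a), float(b)) for a, b in expected]

    @given(
        st.lists(
            st.tuples(st.floats(0, 50), st.floats(0.05, 5)),
            max_size=8,
        )
    )
    def test_idempotent_and_invariants(self, raw):
        iv = sorted((s, s + d) for s, d in raw)
        merged = []
        for s, e in iv:  # make input non-overlapping
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        track = AnnotationTrack(merged)
        once = clean_annotations(track)
        twice = clean_annotations(once)
        assert once.intervals == twice.intervals
        for s, e in once.intervals:
            assert e - s >= 1.0
        for (s1, e1), (s2, e2) in zip(once.intervals, once.intervals[1:]):
            assert s2 - e1 >= 1.0
        # merging never loses annotated time; dropping never adds it
        merged_only = clean_annotations(track, min_episode_s=0.0)
        assert merged_only.total_duration >= track.total_duration - 1e-9
        assert once.total_duration <= merged_only.total_duration + 1e-9


def brute_force_overlap(track, start, end, fs=FS):
    """Per-sample FOG time inside [start, end) counted at the sampling rate."""
    idx = np.arange(int(np.floor(start * fs)), int(np.ceil(end * fs)))
    t = idx / fs
    in_win = (t >= start) & (t < end)
    in_fog = np.zeros_like(t, dtype=bool)
    for s, e in track.intervals:
        in_fog |= (t >= s) & (t < e)
    return np.sum(in_win & in_fog) / fs


class TestMakeWindows:
    def test_test_role_grid(self):
        ws = make_windows(10.0, AnnotationTrack([]), "test")
        assert len(ws) == 5
        np.testing.assert_allclose(ws.starts, [0, 1.5, 3.0, 4.5, 6.0])
        assert not ws.labels.any()

    def test_label_boundary_at_1p5s(self):
        track = AnnotationTrack([(1.0, 2.4)])  # 1.4 s overlap with [0, 3)
        ws = make_windows(3.0, track, "test")
        assert not ws.windows[0].label
        track = AnnotationTrack([(1.0, 2.5)])  # exactly 1.5 s
        ws = make_windows(3.0, track, "test")
        assert ws.windows[0].label
        assert ws.windows[0].fog_overlap_s == pytest.approx(1.5)

    def test_train_role_full_fog_grid(self):
        track = AnnotationTrack([(0.0, 10.0)])
        ws = make_windows(10.0, track, "train")
        assert len(ws) == 12  # floor((10-3)/0.6)+1 starts on the 0.6 s grid
        assert ws.labels.all()
        steps = np.diff(ws.starts)
        np.testing.assert_allclose(steps, TRAIN_FOG_STEP_S)

    def test_train_role_no_fog_grid(self):
        ws = make_windows(10.0, AnnotationTrack([]), "train")
        np.testing.assert_allclose(np.diff(ws.starts), 1.5)
        assert len(ws) == 5

    def test_short_trial_empty(self):
        ws = make_windows(2.0, AnnotationTrack([]), "test")
        assert len(ws) == 0

    def test_windows_stay_inside_trial(self):
        for dur in (3.0, 7.3, 11.9):
            ws = make_windows(dur, AnnotationTrack([]), "test")
            assert all(w.end_s <= dur + 1e-9 for w in ws.windows)

    def test_overlap_matches_brute_force_oracle(self):
        # episode edges snapped to the 128 Hz grid (annotations are
        # frame-quantized), where the per-sample count is exact
        rng = np.random.default_rng(42)
        for _ in range(50):
            dur = rng.uniform(6, 30)
            n_ep = rng.integers(0, 4)
            iv, t0 = [], 0.0
            snap = lambda x: round(x * FS) / FS
            for _ in range(n_ep):
                s = snap(t0 + rng.uniform(0.1, 3))
                e = snap(s + rng.uniform(0.2, 4))
                if e >= dur or e <= s:
                    break
                iv.append((s, e))
                t0 = e
            track = AnnotationTrack(iv)
            for role in ("train", "test"):
                ws = make_windows(dur, track, role)
                for w in ws.windows:
                    bf = brute_force_overlap(track, w.start_s, w.end_s)
                    assert abs(w.fog_overlap_s - bf) <= 1.0 / FS
                    assert w.label == (w.fog_overlap_s >= FOG_OVERLAP_THRESHOLD_S - 1e-9)

    def test_test_windows_tile_timeline(self):
        ws = make_windows(20.0, AnnotationTrack([]), "test")
        starts = ws.starts
        np.testing.assert_allclose(np.diff(starts), TEST_STEP_S)
        # union of windows covers [0, last_start + 3]
        assert starts[0] == 0.0
        assert starts[-1] + 3.0 <= 20.0 + 1e-9
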