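"""Feature library: manifest completeness, spectral estimator behavior,
freezing index, degenerate conventions and invariances."""

import numpy as np
import pytest

from fogkit.features import (
    FINAL_MODEL_FEATURES,
    FREEZE_BAND,
    MANIFEST,
    WALK_BAND,
    band_power,
    compute_features,
    compute_sama_features,
    fit_sama_pca,
    freezing_index,
    psd,
    sama_pca_band_values,
)
from fogkit.signal_model import Site

FS = 128.0
N = 384


def direct_dft_psd(x, fs=FS):
    """Independent PSD oracle: Hann taper + explicit one-sided scaling."""
    from scipy.signal import get_window

    w = get_window("hann", len(x))
    X = np.fft.rfft(x * w)
    p = (np.abs(X) ** 2) / (fs * np.sum(w**2))
    p[1:-1] *= 2.0
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return f, p


def sine(freq, amp=1.0, n=N, fs=FS, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


def window_dict(leg_l=None, leg_r=None, back=None, n=N):
    """Build the per-site window mapping; default zero blocks."""
    z = lambda: np.zeros((3, n))
    return {
        Site.LOWER_BACK: {"accel": back[0] if back else z(), "gyro": back[1] if back else z()},
        Site.LEFT_ANKLE: {"accel": leg_l[0] if leg_l else z(), "gyro": leg_l[1] if leg_l else z()},
        Site.RIGHT_ANKLE: {"accel": leg_r[0] if leg_r else z(), "gyro": leg_r[1] if leg_r else z()},
    }


class TestManifest:
    def test_exactly_86_features(self):
        assert len(MANIFEST) == 86

    def test_final_model_is_14_and_subset(self):
        assert len(FINAL_MODEL_FEATURES) == 14
        assert set(FINAL_MODEL_FEATURES) <= set(MANIFEST.ids)

    def test_ids_unique(self):
        assert len(set(MANIFEST.ids)) == 86


class TestPsd:
    def test_zero_signal_zero_psd(self):
        est = psd(np.zeros(N))
        assert np.all(est.power == 0)

    def test_wrong_length_fatal(self):
        with pytest.raises(ValueError):
            psd(np.zeros(100))

    def test_grid_spans_nyquist(self):
        est = psd(np.zeros(N))
        assert est.frequencies[0] == 0.0
        assert est.frequencies[-1] == pytest.approx(FS / 2)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=N)
        est = psd(x)
        f, p = direct_dft_psd(x)
        np.testing.assert_allclose(est.frequencies, f)
        np.testing.assert_allclose(est.power, p, rtol=1e-9, atol=1e-12)

    def test_sine_power_concentrated(self):
        est = psd(sine(5.0))
        total = band_power(est, (0.0, FS / 2))
        near = band_power(est, (4.0, 6.0))
        assert near / total >= 0.95

    def test_white_noise_flat_on_average(self):
        rng = np.random.default_rng(0)
        acc = np.zeros(N // 2 + 1)
        reps = 200
        for _ in range(reps):
            acc += psd(rng.normal(size=N)).power
        acc /= reps
        # expected density sigma^2/(fs/2) per one-sided bin
        inner = acc[2:-2]
        expect = 1.0 / (FS / 2)
        assert np.abs(np.mean(inner) / expect - 1) < 0.05
        assert np.std(inner) / expect < 0.2

    def test_parseval_within_taper_normalization(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=N)
        est = psd(x)
        from scipy.signal import get_window

        w = get_window("hann", N)
        tapered_power = np.sum((x * w) ** 2) / np.sum(w**2)
        assert np.sum(est.power) * FS / N == pytest.approx(tapered_power, rel=1e-9)


class TestFreezingIndex:
    def test_both_legs_zero_gives_zero(self):
        assert freezing_index(np.zeros(N), np.zeros(N)) == 0.0

    def test_max_over_legs(self):
        fi_5 = freezing_index(sine(5.0), sine(1.0))
        fi_a = freezing_index(sine(5.0), np.zeros(N))
        assert fi_5 == pytest.approx(fi_a)
        assert fi_5 > 2.5 * 10

    def test_walking_frequency_low_fi(self):
        assert freezing_index(sine(1.0), sine(1.0)) < 0.1

    def test_fi_agrees_with_oracle_band_ratio(self):
        # off-grid frequencies so both bands hold real leakage power
        for freq in (1.1, 2.3, 5.2, 6.7):
            x = sine(freq)
            f, p = direct_dft_psd(x)
            m_f = (f >= FREEZE_BAND[0]) & (f <= FREEZE_BAND[1])
            m_w = (f >= WALK_BAND[0]) & (f <= WALK_BAND[1])
            expect = np.trapezoid(p[m_f], f[m_f]) / np.trapezoid(p[m_w], f[m_w])
            assert freezing_index(x, np.zeros(N)) == pytest.approx(expect, rel=1e-9)


class TestComputeFeatures:
    def test_count_is_86(self, sim_trial):
        from fogkit.features import extract_window
        from fogkit.preprocess import lowpass

        filt = lowpass(sim_trial.trial)
        vals = compute_features(extract_window(filt, 0.0), filt.fs)
        assert len(vals) == 86
        assert set(vals) == set(MANIFEST.ids)

    def test_all_zero_window_conventions(self):
        vals = compute_features(window_dict(), FS)
        assert all(np.isfinite(v) for v in vals.values())
        for fid in ("legs_gyro_rms", "back_accel_rms",
                    "ratio_legs_gyro_rms_back_accel_rms",
                    "interleg_corr_gyro_ML", "legs_accel_fi",
                    "back_gyro_entropy_walk"):
            assert vals[fid] == 0.0
        # zero-power peak frequency lands on the band's lower edge
        assert vals["legs_accel_peak_freq_freeze"] == FREEZE_BAND[0]
        assert vals["legs_gyro_peak_freq_walk"] == WALK_BAND[0]

    def test_trembling_vs_walking_separation(self):
        def blocks(freq, leg_amp, back_amp):
            leg = (np.tile(sine(freq, leg_amp), (3, 1)), np.tile(sine(freq, leg_amp * 30), (3, 1)))
            back = (np.tile(sine(freq, back_amp), (3, 1)), np.tile(sine(freq, back_amp * 30), (3, 1)))
            return leg, back

        leg_t, back_t = blocks(5.0, 1.0, 0.05)
        leg_w, back_w = blocks(1.0, 1.0, 0.8)
        tremble = compute_features(window_dict(leg_t, leg_t, back_t), FS)
        walk = compute_features(window_dict(leg_w, leg_w, back_w), FS)
        key = "ratio_legs_gyro_rms_back_accel_rms"
        assert tremble[key] > walk[key]
        assert tremble["legs_accel_fi"] > walk["legs_accel_fi"]
        assert tremble["legs_accel_fi"] > 2.5
        assert walk["legs_accel_fi"] < 2.5

    def test_scale_invariance_and_scaling(self):
        rng = np.random.default_rng(5)
        win = window_dict(
            (rng.normal(size=(3, N)), rng.normal(size=(3, N))),
            (rng.normal(size=(3, N)), rng.normal(size=(3, N))),
            (rng.normal(size=(3, N)), rng.normal(size=(3, N))),
        )
        c = 3.7
        win_c = {
            s: {ch: c * b for ch, b in d.items()} for s, d in win.items()
        }
        v1 = compute_features(win, FS)
        v2 = compute_features(win_c, FS)
        invariant = [
            "interleg_corr_gyro_ML", "interleg_mean_ratio_gyro_ML",
            "legs_accel_fi", "back_accel_fi",
            "legs_accel_peak_freq_freeze", "legs_gyro_peak_freq_walk",
            "back_gyro_entropy_walk", "back_accel_entropy_walk",
            "ratio_legs_gyro_rms_back_accel_rms",
            "ratio_legs_gyro_rms_back_gyro_rms",
        ]
        for fid in invariant:
            assert v2[fid] == pytest.approx(v1[fid], rel=1e-8, abs=1e-10), fid
        scaling = [f for f in MANIFEST.ids if f.endswith(("_sd", "_rms", "_range_cumsum"))
                   and not f.startswith("ratio")]
        for fid in scaling:
            assert v2[fid] == pytest.approx(c * v1[fid], rel=1e-8), fid

    def test_leg_swap_symmetry(self):
        rng = np.random.default_rng(9)
        ll = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        rr = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        back = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        v1 = compute_features(window_dict(ll, rr, back), FS)
        v2 = compute_features(window_dict(rr, ll, back), FS)
        for fid in MANIFEST.ids:
            assert v2[fid] == pytest.approx(v1[fid], rel=1e-10, abs=1e-12), fid

    def test_time_domain_brute_force_agreement(self):
        rng = np.random.default_rng(13)
        ll = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        rr = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        back = (rng.normal(size=(3, N)), rng.normal(size=(3, N)))
        v = compute_features(window_dict(ll, rr, back), FS)
        bk_acc = back[0]
        assert v["back_accel_V_mean"] == pytest.approx(np.mean(bk_acc[0]), abs=1e-8)
        assert v["back_accel_AP_sd"] == pytest.approx(np.std(bk_acc[1]), abs=1e-8)
        assert v["back_gyro_ML_range_cumsum"] == pytest.approx(
            np.ptp(np.cumsum(back[1][2])), abs=1e-8
        )
        # legs: max aggregation by default, min for the designated features
        lv = np.ptp(np.cumsum(ll[0][0]))
        rv = np.ptp(np.cumsum(rr[0][0]))
        assert v["legs_accel_V_range_cumsum"] == pytest.approx(min(lv, rv), abs=1e-8)
        lm = np.sqrt(np.mean(ll[1] ** 2))
        rm = np.sqrt(np.mean(rr[1] ** 2))
        assert v["legs_gyro_rms"] == pytest.approx(max(lm, rm), abs=1e-8)
        bm = np.sqrt(np.mean(back[0] ** 2))
        assert v["ratio_legs_gyro_rms_back_accel_rms"] == pytest.approx(
            max(lm, rm) / bm, abs=1e-8
        )
        ml_l, ml_r = np.mean(ll[1][2]), np.mean(rr[1][2])
        assert v["interleg_mean_ratio_gyro_ML"] == pytest.approx(
            min(abs(ml_l), abs(ml_r)) / max(abs(ml_l), abs(ml_r)), abs=1e-8
        )
        assert v["interleg_corr_gyro_ML"] == pytest.approx(
            np.corrcoef(ll[1][2], rr[1][2])[0, 1], abs=1e-8
        )


class TestSamaFeatures:
    @pytest.fixture
    def pca(self):
        rng = np.random.default_rng(3)
        spectra = np.vstack([
            sama_pca_band_values(rng.normal(size=(3, N))) for _ in range(30)
        ])
        return fit_sama_pca(spectra)

    def test_zero_window_conventions(self, pca):
        vals = compute_sama_features(np.zeros((3, N)), pca=pca)
        for a in ("AP", "V", "ML"):
            assert vals[f"sama_sd_{a}"] == 0.0
        for a, b in (("V", "AP"), ("AP", "ML"), ("V", "ML")):
            assert vals[f"sama_corr_{a}_{b}"] == 0.0

    def test_identical_axes_correlate_fully(self, pca):
        rng = np.random.default_rng(2)
        x = rng.normal(size=N)
        block = np.vstack([x, x, rng.normal(size=N)])
        vals = compute_sama_features(block, pca=pca)
        assert vals["sama_corr_V_AP"] == pytest.approx(1.0)

    def test_two_tone_harmonics(self, pca):
        # 1 Hz strong + 5 Hz weak on every axis -> magnitude signal carries both
        x = sine(1.0, 1.0) + sine(5.0, 0.3)
        block = np.vstack([x, x, x]) + 10.0  # offset keeps the norm signal oscillating
        vals = compute_sama_features(block, pca=pca)
        assert vals["sama_max_harmonic_freq"] == pytest.approx(1.0, abs=0.4)
        assert vals["sama_harmonic_distance"] == pytest.approx(4.0, abs=0.8)

    def test_pca_required(self):
        with pytest.raises(ValueError, match="PCA"):
            compute_sama_features(np.zeros((3, N)), pca=None)

    def test_feature_count(self, pca):
        vals = compute_sama_features(np.random.default_rng(0).normal(size=(3, N)), pca=pca)
        assert len(vals) == 28
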