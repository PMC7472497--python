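"""Per-window feature library.

Implements the 86-feature set used by the windowed FOG classifier, the
freezing index, and the Samà et al. back-sensor comparator set.

Sensor groups
-------------
Features are organised by sensor group: ``back_accel``, ``back_gyro``,
``legs_accel``, ``legs_gyro``. Leg-sourced features are computed per leg and
aggregated across the two ankles — max by default, min where the final-model
table specifies it — so every leg feature is invariant to swapping the legs.

Canonical manifest (86 features)
--------------------------------
- per group x per axis (V, AP, ML) x {mean, SD, skewness, range of
  cumulative sum}                                         4*3*4 = 48
- tri-axial RMS per group                                          4
- per group, seven spectral features on the group's designated axis
  (freezing index always on AP; band powers, peak frequencies and
  spectral entropies in the walk band 0.5-3 Hz and freeze band 3-8 Hz
  on back_accel:AP, back_gyro:V, legs_accel:V, legs_gyro:V)   7*4 = 28
- inter-leg correlation of gyro ML                                 1
- inter-leg mean-magnitude min/max ratio of gyro ML                1
- spectral skewness 0.5-3 Hz of back_accel:AP and back_gyro:ML     2
- cross-sensor RMS ratios: max-leg gyro tri-axial RMS over back
  accel RMS, and over back gyro RMS                                2

Degenerate conventions: 0/0 ratios (and any zero denominator) give 0,
correlations with a zero-variance input give 0, spectral entropy of a
zero-power band gives 0, and the peak frequency of a zero-power band is
the band's lower edge. These make the all-zero window map to an all-zero,
finite feature vector.

The freezing index of a window is the ratio of integrated power spectral
density in the freeze band (3-8 Hz) to that in the walk band (0.5-3 Hz) of
a leg's anterior-posterior acceleration, with the maximum over the two legs
taken; the classic threshold detector fires at FI > 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .signal_model import AXES, FeatureManifest, FeatureSpec, Site, TrialRecording

WALK_BAND = (0.5, 3.0)
FREEZE_BAND = (3.0, 8.0)
FI_THRESHOLD = 2.5

WINDOW_SAMPLES = 384  # 3 s at 128 Hz

_GROUPS = ("back_accel", "back_gyro", "legs_accel", "legs_gyro")
_GROUP_SITECHAN = {
    "back_accel": ((Site.LOWER_BACK,), "accel"),
    "back_gyro": ((Site.LOWER_BACK,), "gyro"),
    "legs_accel": ((Site.LEFT_ANKLE, Site.RIGHT_ANKLE), "accel"),
    "legs_gyro": ((Site.LEFT_ANKLE, Site.RIGHT_ANKLE), "gyro"),
}
#: Axis on which each group's spectral features (other than FI) are computed.
_SPECTRAL_AXIS = {
    "back_accel": "AP",
    "back_gyro": "V",
    "legs_accel": "V",
    "legs_gyro": "V",
}
#: Leg-aggregation exceptions (feature_id -> 'min'); everything else uses max.
_MIN_AGGREGATED = {
    "legs_accel_V_range_cumsum": "min",
    "legs_gyro_ML_range_cumsum": "min",
}

_STATS = ("mean", "sd", "skew", "range_cumsum")
_SPECTRAL_KINDS = (
    "fi",
    "band_power_walk",
    "band_power_freeze",
    "peak_freq_walk",
    "peak_freq_freeze",
    "entropy_walk",
    "entropy_freeze",
)


def build_manifest() -> FeatureManifest:
    """The canonical 86-entry feature manifest."""
    entries: list[FeatureSpec] = []
    for g in _GROUPS:
        src = "legs" if g.startswith("legs") else "back"
        chan = g.split("_")[1]
        for ax in AXES:
            for stat in _STATS:
                fid = f"{g}_{ax}_{stat}"
                agg = _MIN_AGGREGATED.get(fid, "max") if src == "legs" else None
                entries.append(FeatureSpec(fid, src, chan, ax, "time", None, agg))
    for g in _GROUPS:
        src = "legs" if g.startswith("legs") else "back"
        chan = g.split("_")[1]
        entries.append(
            FeatureSpec(f"{g}_rms", src, chan, "VAPML", "time", None,
                        "max" if src == "legs" else None)
        )
    for g in _GROUPS:
        src = "legs" if g.startswith("legs") else "back"
        chan = g.split("_")[1]
        agg = "max" if src == "legs" else None
        for kind in _SPECTRAL_KINDS:
            axis = "AP" if kind == "fi" else _SPECTRAL_AXIS[g]
            if kind == "fi":
                band = None
            elif kind.endswith("walk"):
                band = WALK_BAND
            else:
                band = FREEZE_BAND
            entries.append(FeatureSpec(f"{g}_{kind}", src, chan, axis, "frequency", band, agg))
    entries.append(FeatureSpec("interleg_corr_gyro_ML", "legs", "gyro", "ML", "time"))
    entries.append(FeatureSpec("interleg_mean_ratio_gyro_ML", "legs", "gyro", "ML", "time"))
    entries.append(
        FeatureSpec("back_accel_AP_spectral_skew_walk", "back", "accel", "AP",
                    "frequency", WALK_BAND)
    )
    entries.append(
        FeatureSpec("back_gyro_ML_spectral_skew_walk", "back", "gyro", "ML",
                    "frequency", WALK_BAND)
    )
    entries.append(
        FeatureSpec("ratio_legs_gyro_rms_back_accel_rms", "legs_and_back",
                    "accel+gyro", "VAPML", "time", None, "max")
    )
    entries.append(
        FeatureSpec("ratio_legs_gyro_rms_back_gyro_rms", "legs_and_back",
                    "gyro", "VAPML", "time", None, "max")
    )
    return FeatureManifest(entries)


#: The 14 features of the final detection model, in their model-importance order.
FINAL_MODEL_FEATURES: tuple[str, ...] = (
    "ratio_legs_gyro_rms_back_accel_rms",
    "legs_accel_fi",
    "legs_accel_peak_freq_freeze",
    "back_gyro_entropy_walk",
    "legs_gyro_peak_freq_walk",
    "back_gyro_ML_range_cumsum",
    "back_accel_entropy_walk",
    "legs_accel_V_range_cumsum",
    "interleg_mean_ratio_gyro_ML",
    "back_gyro_ML_spectral_skew_walk",
    "interleg_corr_gyro_ML",
    "ratio_legs_gyro_rms_back_gyro_rms",
    "legs_gyro_ML_range_cumsum",
    "legs_gyro_rms",
)

MANIFEST = build_manifest()


# --------------------------------------------------------------------------
# Spectral primitives


@dataclass
class SpectralEstimate:
    """Single-axis PSD of one window (frequencies in Hz, power >= 0)."""

    frequencies: np.ndarray
    power: np.ndarray


def psd(x: np.ndarray, fs: float = 128.0, n_expected: int = WINDOW_SAMPLES) -> SpectralEstimate:
    """Hann-tapered single-segment periodogram of one window axis.

    3-second windows are too short for multi-segment averaging, so a single
    tapered periodogram is used.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != n_expected:
        raise ValueError(f"expected a {n_expected}-sample axis signal, got shape {x.shape}")
    f, p = sp_signal.periodogram(x, fs=fs, window="hann", detrend=False)
    return SpectralEstimate(frequencies=f, power=p)


def band_power(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over the band, edges inclusive."""
    lo, hi = band
    m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(est.power[m], est.frequencies[m]))


def peak_frequency(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """Frequency of maximum PSD inside the band; lower edge for zero power."""
    lo, hi = band
    m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
    if not m.any() or not np.any(est.power[m] > 0):
        return float(lo)
    f, p = est.frequencies[m], est.power[m]
    return float(f[np.argmax(p)])


def spectral_entropy(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """Shannon entropy (nats) of the PSD normalized to sum 1 within the band."""
    lo, hi = band
    m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
    p = est.power[m]
    tot = p.sum()
    if tot <= 0:
        return 0.0
    q = p[p > 0] / tot
    return float(-(q * np.log(q)).sum())


def spectral_skewness(est: SpectralEstimate, band: tuple[float, float]) -> float:
    lo, hi = band
    m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
    return _safe_skew(est.power[m])


def freezing_index_1d(x: np.ndarray, fs: float = 128.0) -> float:
    """Freeze-band over walk-band power ratio for one axis signal."""
    est = psd(x, fs, n_expected=len(x))
    num = band_power(est, FREEZE_BAND)
    den = band_power(est, WALK_BAND)
    return _safe_ratio(num, den)


def freezing_index(left_ap: np.ndarray, right_ap: np.ndarray, fs: float = 128.0) -> float:
    """Max over the two legs of the AP-acceleration freezing index."""
    return max(freezing_index_1d(left_ap, fs), freezing_index_1d(right_ap, fs))


# --------------------------------------------------------------------------
# Scalar helpers with degenerate conventions


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0:
        return 0.0
    return float(num / den)


def _safe_skew(x: np.ndarray) -> float:
    # Fisher-Pearson g1 = m3 / m2^(3/2), matching scipy.stats.skew(bias=True),
    # computed directly to avoid wrapper overhead in the per-window hot loop.
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return 0.0
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0.0:
        return 0.0
    return float(np.mean(d * d * d) / m2**1.5)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _rms(block: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(block))))


def _range_cumsum(x: np.ndarray) -> float:
    return float(np.ptp(np.cumsum(x)))


# --------------------------------------------------------------------------
# Window extraction and the full feature set


def extract_window(trial: TrialRecording, start_s: float, length_s: float = 3.0
                   ) -> dict[Site, dict[str, np.ndarray]]:
    """Slice the (3, n) accel/gyro blocks of every site for one window."""
    i0 = int(round(start_s * trial.fs))
    n = int(round(length_s * trial.fs))
    if i0 < 0 or i0 + n > trial.n_samples:
        raise ValueError(f"window [{start_s}, {start_s + length_s}) outside trial")
    out: dict[Site, dict[str, np.ndarray]] = {}
    for site, rec in trial.recordings.items():
        out[site] = {"accel": rec.accel[:, i0:i0 + n], "gyro": rec.gyro[:, i0:i0 + n]}
    return out


def _group_blocks(win: Mapping[Site, Mapping[str, np.ndarray]], group: str
                  ) -> list[np.ndarray]:
    sites, chan = _GROUP_SITECHAN[group]
    return [np.asarray(win[s][chan]) for s in sites]


def _agg(values: Sequence[float], agg: str | None) -> float:
    if agg == "min":
        return float(min(values))
    if agg == "max":
        return float(max(values))
    (v,) = values
    return float(v)


def compute_features(
    win: Mapping[Site, Mapping[str, np.ndarray]],
    fs: float = 128.0,
    manifest: FeatureManifest = MANIFEST,
) -> dict[str, float]:
    """Compute the full 86-feature vector for one window.

    ``win`` maps each site to its (3, n) 'accel' and 'gyro' blocks, rows
    ordered (V, AP, ML), as produced by :func:`extract_window`.
    """
    stat_fn = {
        "mean": lambda x: float(np.mean(x)),
        "sd": lambda x: float(np.std(x)),
        "skew": _safe_skew,
        "range_cumsum": _range_cumsum,
    }
    psd_cache: dict[tuple, SpectralEstimate] = {}

    def _psd(group: str, leg_idx: int, axis: str) -> SpectralEstimate:
        key = (group, leg_idx, axis)
        if key not in psd_cache:
            block = _group_blocks(win, group)[leg_idx]
            psd_cache[key] = psd(block[AXES.index(axis)], fs, n_expected=block.shape[1])
        return psd_cache[key]

    values: dict[str, float] = {}
    for spec in manifest.entries:
        fid = spec.feature_id
        g = None
        for cand in _GROUPS:
            if fid.startswith(cand):
                g = cand
                break
        if spec.domain == "time" and g is not None and fid != f"{g}_rms":
            # per-axis statistic: fid is "<group>_<axis>_<stat>"
            axis, stat = fid.removeprefix(f"{g}_").split("_", 1)
            blocks = _group_blocks(win, g)
            per_leg = [stat_fn[stat](b[AXES.index(axis)]) for b in blocks]
            values[fid] = _agg(per_leg, spec.leg_agg)
        elif g is not None and fid == f"{g}_rms":
            blocks = _group_blocks(win, g)
            values[fid] = _agg([_rms(b) for b in blocks], spec.leg_agg)
        elif g is not None and spec.domain == "frequency":
            kind = fid.removeprefix(f"{g}_")
            blocks = _group_blocks(win, g)
            per_leg = []
            for i in range(len(blocks)):
                est = _psd(g, i, spec.axis)
                if kind == "fi":
                    per_leg.append(_safe_ratio(band_power(est, FREEZE_BAND),
                                               band_power(est, WALK_BAND)))
                elif kind.startswith("band_power"):
                    per_leg.append(band_power(est, spec.band))
                elif kind.startswith("peak_freq"):
                    per_leg.append(peak_frequency(est, spec.band))
                elif kind.startswith("entropy"):
                    per_leg.append(spectral_entropy(est, spec.band))
                else:  # spectral skew features carry the group prefix too
                    per_leg.append(spectral_skewness(est, spec.band))
            values[fid] = _agg(per_leg, spec.leg_agg)
        elif fid == "interleg_corr_gyro_ML":
            l = win[Site.LEFT_ANKLE]["gyro"][AXES.index("ML")]
            r = win[Site.RIGHT_ANKLE]["gyro"][AXES.index("ML")]
            values[fid] = _safe_corr(l, r)
        elif fid == "interleg_mean_ratio_gyro_ML":
            ml = abs(float(np.mean(win[Site.LEFT_ANKLE]["gyro"][AXES.index("ML")])))
            mr = abs(float(np.mean(win[Site.RIGHT_ANKLE]["gyro"][AXES.index("ML")])))
            values[fid] = _safe_ratio(min(ml, mr), max(ml, mr))
        elif fid == "ratio_legs_gyro_rms_back_accel_rms":
            legs = max(_rms(win[s]["gyro"]) for s in (Site.LEFT_ANKLE, Site.RIGHT_ANKLE))
            values[fid] = _safe_ratio(legs, _rms(win[Site.LOWER_BACK]["accel"]))
        elif fid == "ratio_legs_gyro_rms_back_gyro_rms":
            legs = max(_rms(win[s]["gyro"]) for s in (Site.LEFT_ANKLE, Site.RIGHT_ANKLE))
            values[fid] = _safe_ratio(legs, _rms(win[Site.LOWER_BACK]["gyro"]))
        else:
            raise KeyError(f"unhandled feature id {fid}")

    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite feature value(s): {bad}")
    return values


# --------------------------------------------------------------------------
# Samà et al. comparator feature set (back accelerometer only)

SAMA_BANDS_SD = ((0.04, 0.68), (0.68, 3.0), (3.0, 8.0), (8.0, 20.0), (0.1, 8.0))
SAMA_BANDS_SKEW = ((0.04, 0.68), (0.68, 3.0), (3.0, 8.0))
SAMA_PCA_BAND = (0.04, 8.0)

_SAMA_MEAN_DIFFS = (("AP", "V"), ("V", "ML"), ("AP", "ML"))
_SAMA_CORRS = (("V", "AP"), ("AP", "ML"), ("V", "ML"))


@dataclass
class SamaPCA:
    """PCA basis over the 0.04-8 Hz spectrum, fit on training windows only."""

    mean: np.ndarray
    components: np.ndarray  # (3, n_bins)

    def project(self, spectrum: np.ndarray) -> np.ndarray:
        return (spectrum - self.mean) @ self.components.T


def _sama_spectrum(back_accel: np.ndarray, fs: float) -> SpectralEstimate:
    """PSD of the mean-removed per-sample Euclidean norm of the three axes.

    The mean is removed so that leakage from the large quasi-constant
    magnitude (gravity) does not dominate the harmonic features.
    """
    mag = np.linalg.norm(np.asarray(back_accel, float), axis=0)
    return psd(mag - mag.mean(), fs, n_expected=back_accel.shape[1])


def sama_pca_band_values(back_accel: np.ndarray, fs: float = 128.0) -> np.ndarray:
    est = _sama_spectrum(back_accel, fs)
    m = (est.frequencies >= SAMA_PCA_BAND[0] - 1e-12) & (est.frequencies <= SAMA_PCA_BAND[1] + 1e-12)
    return est.power[m]


def fit_sama_pca(training_spectra: np.ndarray) -> SamaPCA:
    """Fit the 3-component spectral PCA basis on training-window spectra."""
    from sklearn.decomposition import PCA

    n_comp = min(3, training_spectra.shape[0], training_spectra.shape[1])
    p = PCA(n_components=n_comp, svd_solver="full").fit(training_spectra)
    comp = p.components_
    if n_comp < 3:
        comp = np.vstack([comp, np.zeros((3 - n_comp, training_spectra.shape[1]))])
    return SamaPCA(mean=p.mean_, components=comp)


def compute_sama_features(
    back_accel: np.ndarray,
    fs: float = 128.0,
    pca: SamaPCA | None = None,
) -> dict[str, float]:
    """The Samà et al. comparator features from the back accelerometer.

    Time-domain features operate on the per-axis signals; frequency-domain
    features operate on the PSD of the per-sample norm of the three axes.
    The three spectral PCA projections require ``pca`` (fit on training
    windows); passing None raises, because a test-time vector without the
    learned basis would be incomplete.
    """
    if pca is None:
        raise ValueError("Samà PCA basis is required; fit it on training windows first")
    back_accel = np.asarray(back_accel, dtype=float)
    ax = {a: back_accel[AXES.index(a)] for a in AXES}
    out: dict[str, float] = {}
    for a, b in _SAMA_MEAN_DIFFS:
        out[f"sama_mean_diff_{a}_{b}"] = float(np.mean(ax[a]) - np.mean(ax[b]))
    for a in ("AP", "V", "ML"):
        out[f"sama_sd_{a}"] = float(np.std(ax[a]))
    for a, b in _SAMA_CORRS:
        out[f"sama_corr_{a}_{b}"] = _safe_corr(ax[a], ax[b])
    for a in ("AP", "V", "ML"):
        out[f"sama_skew_{a}"] = _safe_skew(ax[a])
    mag = np.linalg.norm(back_accel, axis=0)
    out["sama_skew_rms"] = _safe_skew(mag)

    est = _sama_spectrum(back_accel, fs)
    for lo, hi in SAMA_BANDS_SD:
        m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
        out[f"sama_band_sd_{lo:g}_{hi:g}"] = float(np.std(est.power[m]))
    f1, p1, f2 = _two_max_harmonics(est)
    out["sama_max_harmonic"] = p1
    out["sama_max_harmonic_freq"] = f1
    out["sama_harmonic_distance"] = abs(f1 - f2) if f2 == f2 else 0.0
    tot = est.power[1:].sum()
    out["sama_center_of_mass"] = (
        float((est.frequencies[1:] * est.power[1:]).sum() / tot) if tot > 0 else 0.0
    )
    for lo, hi in SAMA_BANDS_SKEW:
        m = (est.frequencies >= lo - 1e-12) & (est.frequencies <= hi + 1e-12)
        out[f"sama_band_skew_{lo:g}_{hi:g}"] = _safe_skew(est.power[m])
    proj = pca.project(sama_pca_band_values(back_accel, fs))
    for i in range(3):
        out[f"sama_pca_{i + 1}"] = float(proj[i])
    return out


def _two_max_harmonics(est: SpectralEstimate) -> tuple[float, float, float]:
    """Frequencies/value of the two largest local PSD peaks (DC excluded).

    Returns (f_max, p_max, f_second); f_second is NaN when no second peak
    exists; for an all-zero spectrum all values are 0/NaN-safe.
    """
    p = est.power.copy()
    p[0] = 0.0
    if not np.any(p > 0):
        return 0.0, 0.0, float("nan")
    peaks, _ = sp_signal.find_peaks(p)
    if len(peaks) == 0:
        i = int(np.argmax(p))
        return float(est.frequencies[i]), float(p[i]), float("nan")
    order = peaks[np.argsort(p[peaks])[::-1]]
    f1, p1 = float(est.frequencies[order[0]]), float(p[order[0]])
    if len(order) < 2:
        return f1, p1, float("nan")
    return f1, p1, float(est.frequencies[order[1]])
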