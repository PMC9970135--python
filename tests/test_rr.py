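"""Respiratory-rate chain: baseline, PCA, thresholds, spectrum, breaths."""

import numpy as np
import pytest
from scipy.signal import get_window

from conftest import sinusoid
from quatresp.errors import (
    BandError,
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
)
from quatresp.io import trim_window
from quatresp.rr import (
    PRESETS,
    CompartmentSignal,
    RRConfig,
    ThresholdEstimate,
    apply_bandpass,
    compute_threshold,
    design_bandpass,
    detect_breaths,
    estimate_rr,
    extract_pc1,
    merge_thresholds,
    remove_baseline,
    threshold_from_stats,
    welch_find_peak,
)

FS = 10.0


def _sig(x, compartment="thorax", fs=FS):
    return CompartmentSignal(samples=np.asarray(x, float), fs=fs, compartment=compartment)


# ---------------------------------------------------------------------------
# baseline removal


def moving_average_oracle(x, window):
    """Direct edge-shrunk centered moving average, one explicit loop."""
    x = np.asarray(x, float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def test_remove_baseline_zeroes_constant_components():
    q = np.tile([0.7, 0.1, -0.2, 0.3], (500, 1))
    assert np.allclose(remove_baseline(q, 97), 0.0, atol=1e-12)


def test_remove_baseline_matches_convolution_oracle(rng):
    q = rng.normal(size=(500, 4))
    got = remove_baseline(q, 97)
    for c in range(4):
        expected = q[:, c] - moving_average_oracle(q[:, c], 97)
        assert np.max(np.abs(got[:, c] - expected)) <= 1e-12


def test_remove_baseline_keeps_oscillation_removes_offset():
    _, s = sinusoid(0.25, 60.0)
    q = np.column_stack([s + 0.3, s, s, s])
    out = remove_baseline(q, 97)
    # DC offset gone; the sinusoid survives with the known moving-average gain
    assert abs(out[:, 0].mean()) < 1e-2
    expected = (s + 0.3) - moving_average_oracle(s + 0.3, 97)
    assert np.max(np.abs(out[:, 0] - expected)) <= 1e-12


def test_remove_baseline_needs_enough_samples():
    with pytest.raises(InsufficientDataError):
        remove_baseline(np.zeros((50, 4)), 97)


def test_remove_baseline_window_must_be_odd():
    with pytest.raises(ConfigError):
        remove_baseline(np.zeros((500, 4)), 96)


# ---------------------------------------------------------------------------
# PCA respiratory signal


def test_pc1_recovers_single_active_component():
    _, s = sinusoid(0.25, 50.0)
    comps = np.column_stack([s, np.zeros_like(s), np.zeros_like(s), np.zeros_like(s)])
    sig = extract_pc1(comps, FS)
    assert sig.variance_explained == pytest.approx(1.0)
    assert np.allclose(sig.samples, s - s.mean(), atol=1e-12)


def test_pc1_matches_eigendecomposition_oracle(rng):
    X = rng.normal(size=(500, 4)) @ rng.normal(size=(4, 4))
    sig = extract_pc1(X, FS)
    # independent oracle: leading eigenvector of the sample covariance
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (Xc.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    proj = Xc @ v[:, -1]
    err_same = np.max(np.abs(sig.samples - proj))
    err_flip = np.max(np.abs(sig.samples + proj))
    scale = np.max(np.abs(proj))
    assert min(err_same, err_flip) / scale <= 1e-8
    assert sig.variance_explained == pytest.approx(w[-1] / w.sum())


def test_pc1_sign_is_deterministic(rng):
    X = rng.normal(size=(300, 4))
    a = extract_pc1(X, FS)
    b = extract_pc1(X.copy(), FS)
    assert np.array_equal(a.samples, b.samples)
    # orientation rule: non-negative correlation with the first component
    Xc = X - X.mean(axis=0)
    assert Xc[:, 0] @ a.samples >= 0


def test_pc1_rejects_constant_input():
    with pytest.raises(DegenerateInputError):
        extract_pc1(np.ones((100, 4)), FS)


# ---------------------------------------------------------------------------
# thresholds


@pytest.mark.parametrize(
    "f_mean, f_std, preset, expected",
    [
        (0.3, 0.1, "static", 0.2),  # mean − std above the floor
        (0.25, 0.24, "walking", 0.2),  # floor binds
        (0.5, 0.05, "running", 0.45),
    ],
)
def test_threshold_formula_substitution(f_mean, f_std, preset, expected):
    assert threshold_from_stats(f_mean, f_std, PRESETS[preset]) == pytest.approx(expected)


def test_threshold_from_clean_sinusoid_peak_spacing():
    _, s = sinusoid(0.25, 120.0)
    est = compute_threshold(_sig(s), PRESETS["static"])
    # peak spacing is quantized to the 10 Hz grid: one step at 4 s spacing
    assert abs(est.f_mean - 0.25) < FS / (0.25 * FS * 40) * 0.25 + 1e-6
    assert est.f_std < 0.01
    assert not est.fallback
    assert est.f_thresh >= PRESETS["static"].f_thresh_min


def test_threshold_falls_back_with_too_few_peaks():
    est = compute_threshold(_sig(np.zeros(100)), PRESETS["walking"])
    assert est.fallback
    assert est.f_thresh == PRESETS["walking"].f_thresh_min


def test_merge_thresholds_takes_minimum(rng):
    def te(f):
        return ThresholdEstimate(f_mean=f, f_std=0.0, f_thresh=f, compartment="thorax")

    assert merge_thresholds(te(0.20), te(0.15)) == 0.15
    assert merge_thresholds(te(0.05), te(0.05)) == 0.05
    for _ in range(25):
        a, b = rng.uniform(0.05, 1.0, 2)
        m = merge_thresholds(te(a), te(b))
        assert m <= a and m <= b


# ---------------------------------------------------------------------------
# Welch peak search


def welch_oracle(x, fs, nperseg=300, noverlap=50):
    """Segment-averaged Hamming periodogram, built from first principles."""
    x = np.asarray(x, float)
    win = get_window("hamming", nperseg)
    step = nperseg - noverlap
    scale = 1.0 / (fs * np.sum(win**2))
    segments = []
    for start in range(0, x.size - nperseg + 1, step):
        seg = x[start : start + nperseg]
        seg = (seg - seg.mean()) * win
        spec = np.fft.rfft(seg)
        p = scale * np.abs(spec) ** 2
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        segments.append(p)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.mean(segments, axis=0)


def test_welch_matches_segment_averaged_periodogram_oracle(rng):
    x = rng.normal(size=500)
    search = welch_find_peak(_sig(x), 0.05, 1.0)
    freqs, psd = welch_oracle(x, FS)
    assert np.allclose(search.freqs, freqs, atol=1e-12)
    assert np.max(np.abs(search.psd - psd)) / np.max(psd) <= 1e-8


def test_welch_peak_on_pure_sinusoid():
    _, s = sinusoid(0.25, 600.0)
    search = welch_find_peak(_sig(s), 0.05, 1.0)
    assert abs(search.f_peak - 0.25) <= FS / 300  # within one frequency bin


def test_welch_band_excludes_low_frequency_artifact():
    t, breath = sinusoid(0.4, 600.0, amplitude=0.3)
    artifact = 3.0 * np.sin(2 * np.pi * 0.05 * t)
    search = welch_find_peak(_sig(breath + artifact), 0.2, 0.75)
    assert abs(search.f_peak - 0.4) <= FS / 300


def test_welch_rejects_inverted_band():
    with pytest.raises(BandError):
        welch_find_peak(_sig(np.zeros(600)), 0.8, 0.75)


def test_welch_needs_one_full_window():
    with pytest.raises(InsufficientDataError, match="spectrum"):
        welch_find_peak(_sig(np.zeros(200)), 0.05, 1.0)


# ---------------------------------------------------------------------------
# adaptive band-pass


@pytest.mark.parametrize(
    "f_peak, thresh, f_l, f_u",
    [
        (0.25, 0.20, 0.21, 0.29),
        (0.22, 0.20, 0.20, 0.26),  # the merged-threshold floor binds
    ],
)
def test_band_edges_substitution(f_peak, thresh, f_l, f_u):
    band = design_bandpass(f_peak, thresh)
    assert band.f_U == pytest.approx(f_u)
    assert band.f_L == pytest.approx(f_l)
    assert band.f_L < band.f_peak < band.f_U or band.f_L == pytest.approx(thresh)


def test_band_degenerates_when_threshold_tops_upper_edge():
    with pytest.raises(BandError):
        design_bandpass(0.10, 0.20)


def test_bandpass_preserves_center_frequency_sinusoid():
    _, s = sinusoid(0.25, 300.0)
    band = design_bandpass(0.25, 0.20)
    out = apply_bandpass(_sig(s), band)
    core = slice(300, 2700)  # ignore filter edge transients
    ratio = np.max(np.abs(out.samples[core])) / np.max(np.abs(s[core]))
    assert 0.95 < ratio < 1.05


def test_bandpass_rejects_out_of_band_sinusoid():
    _, s = sinusoid(1.5, 300.0)
    band = design_bandpass(0.25, 0.21)
    out = apply_bandpass(_sig(s), band)
    assert np.sqrt(np.mean(out.samples**2)) < 0.05 * np.sqrt(np.mean(s**2))


def test_bandpass_of_zero_is_zero():
    band = design_bandpass(0.25, 0.20)
    out = apply_bandpass(_sig(np.zeros(600)), band)
    assert np.allclose(out.samples, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# breath detection


def test_breath_count_on_clean_quarter_hertz_minute():
    _, s = sinusoid(0.25, 60.0)
    table = detect_breaths(_sig(s), 0.25)
    assert abs(table.n_breaths + 1 - 15) <= 1  # 15 ± 1 maxima
    assert np.all((table.rr_bpm >= 14) & (table.rr_bpm <= 16))


def test_jitter_below_prominence_does_not_add_breaths(rng):
    t, s = sinusoid(0.25, 60.0)
    clean = detect_breaths(_sig(s), 0.25)
    jittered = s + 0.02 * np.sin(2 * np.pi * 2.4 * t)  # tiny fast ripple
    noisy = detect_breaths(_sig(jittered), 0.25)
    assert noisy.peak_times.size == clean.peak_times.size


def test_flat_signal_yields_empty_flagged_table():
    table = detect_breaths(_sig(np.zeros(600)), 0.25)
    assert table.n_breaths == 0
    assert "no_breaths" in table.flags


# ---------------------------------------------------------------------------
# full chain


def test_estimate_rr_recovers_static_truth(static_recording):
    rec, truth = static_recording
    rec = trim_window(rec, 30.0, rec.duration)
    result = estimate_rr(rec, "static")
    for comp in ("thorax", "abdomen", "sum"):
        assert result.medians[comp] == pytest.approx(15.0, abs=1.0)
    assert result.quality == "ok"


def test_estimate_rr_median_lies_inside_fitted_band(static_recording):
    rec, _ = static_recording
    rec = trim_window(rec, 30.0, rec.duration)
    result = estimate_rr(rec, "static")
    for comp, band in result.bands.items():
        assert 60.0 * band.f_L <= result.medians[comp] <= 60.0 * band.f_U


def test_estimate_rr_is_deterministic(static_recording):
    rec, _ = static_recording
    rec = trim_window(rec, 30.0, rec.duration)
    a = estimate_rr(rec, "static")
    b = estimate_rr(rec, "static")
    assert a.medians == b.medians
    for comp in a.breaths:
        assert np.array_equal(a.breaths[comp].peak_times, b.breaths[comp].peak_times)
        assert np.array_equal(a.breaths[comp].rr_bpm, b.breaths[comp].rr_bpm)


def test_estimate_rr_monotone_in_true_rate():
    """Estimated medians increase strictly with true RR under matched presets."""
    from quatresp.simulate import Scenario, simulate_recording

    cases = [
        (12.0, "static", "sitting_no_support"),
        (15.0, "static", "supine"),
        (20.0, "static", "standing"),
        (30.0, "walking", "walking_6kmh"),
        (40.0, "cycling", "cycling"),
        (50.0, "running", "running"),
    ]
    medians = []
    for i, (rr_true, preset, activity) in enumerate(cases):
        rec, _ = simulate_recording(
            Scenario(activity=activity, rr_true=rr_true, seed=100 + i, dropout_rate=0.0)
        )
        rec = trim_window(rec, 30.0, rec.duration)
        medians.append(estimate_rr(rec, preset).medians["sum"])
    assert np.all(np.diff(medians) > 0)


def test_estimate_rr_short_recording_names_spectrum_stage():
    from quatresp.simulate import Scenario, simulate_recording

    rec, _ = simulate_recording(
        Scenario(activity="standing", rr_true=15.0, duration=25.0, seed=1, dropout_rate=0.0)
    )
    with pytest.raises(InsufficientDataError, match="spectrum"):
        estimate_rr(rec, "static")


def test_stairs_recording_raises_low_snr_quality():
    """Stair climbing's non-shared wobble drives the PSD peak under the SNR floor."""
    from quatresp.simulate import Scenario, simulate_recording

    rec, _ = simulate_recording(
        Scenario(activity="stairs", rr_true=24.0, seed=21, dropout_rate=0.0)
    )
    rec = trim_window(rec, 30.0, rec.duration)
    result = estimate_rr(rec, "walking")
    assert result.quality == "low_snr"


def test_unknown_preset_rejected(static_recording):
    rec, _ = static_recording
    with pytest.raises(ConfigError, match="sprinting"):
        estimate_rr(rec, "sprinting")
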