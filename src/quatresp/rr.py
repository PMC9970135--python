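"""Breath-by-breath respiratory-rate estimation from referenced quaternions.

The estimation chain, run independently for the thoracic and abdominal
compartments and for their sum:

1.  *Pre-processing* — express each chest-wall unit in the reference-unit
    frame (trunk motion cancels), then remove the residual slow baseline with
    a 97-sample centered moving average per quaternion component.
2.  *Dimension reduction* — project the four components onto their first
    principal component; that waveform is the respiratory signal.
3.  *Spectrum analysis* — smooth (Savitzky–Golay, order 3, window 31), locate
    peaks, and turn the inverse inter-peak intervals into a frequency floor
    ``f_thresh = max(f_thresh_min, f_mean − f_std)`` per compartment; merge
    the two floors by taking their minimum; find the dominant respiratory
    frequency ``f_peak`` as the Welch-PSD maximum (Hamming window, 300
    samples, 50 overlap) inside ``[f_merged, f_search_max]``.
4.  *Processing* — band-pass ``[max(f_merged, f_peak−0.04), f_peak+0.04]`` Hz
    (zero-phase Butterworth), smooth again with an ``f_peak``-tuned
    Savitzky–Golay window, detect maxima/minima with an ``f_peak``-tuned
    minimum distance and prominence, and report RR = 60 / inter-maximum
    interval, breath by breath.

The per-activity floors and search ceilings live in :data:`PRESETS`: static
postures (0.05 Hz floor, 1 Hz ceiling), walking/cycling (0.2, 0.75), running
(0.4, 1.4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA

from .errors import BandError, ConfigError, DegenerateInputError, InsufficientDataError
from .io import Recording
from .quaternions import QuaternionSeries, relative_series

# ---------------------------------------------------------------------------
# presets and configuration


@dataclass(frozen=True)
class ActivityPreset:
    """Per-activity frequency bounds for the respiratory-peak search."""

    name: str
    f_thresh_min: float  # Hz, floor of the low-frequency threshold
    f_search_max: float  # Hz, ceiling of the PSD peak search

    def __post_init__(self):
        if not (0.0 < self.f_thresh_min < self.f_search_max):
            raise ConfigError(f"invalid preset bounds for {self.name!r}")


PRESETS = {
    "static": ActivityPreset("static", 0.05, 1.0),
    "walking": ActivityPreset("walking", 0.2, 0.75),
    "cycling": ActivityPreset("cycling", 0.2, 0.75),
    "running": ActivityPreset("running", 0.4, 1.4),
}


@dataclass
class RRConfig:
    """Tunable parameters of the RR chain (defaults are the validated ones)."""

    baseline_window: int = 97  # samples, centered moving average
    sg_window: int = 31  # first Savitzky–Golay pass
    sg_order: int = 3
    welch_nperseg: int = 300  # samples (30 s at 10 Hz)
    welch_noverlap: int = 50
    band_half_width: float = 0.04  # Hz, adaptive band edges around f_peak
    # parametric tuning of the second smoothing / peak detection stage
    tune_window_factor: float = 0.6  # SG window ≈ factor·fs/f_peak samples
    tune_distance_factor: float = 0.5  # min peak distance ≈ factor/f_peak s
    tune_prominence_factor: float = 0.2  # × std of the band-passed signal
    threshold_prominence_factor: float = 0.25  # peak floor in compute_threshold
    snr_floor: float = 3.0  # PSD peak / median in-band PSD below -> low_snr
    butter_order: int = 2  # applied forward-backward (effective order 4)
    merged_threshold_mode: str = "merged"  # or "per_compartment"

    @classmethod
    def from_dict(cls, d: dict) -> "RRConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown RR config keys: {sorted(unknown)}")
        return cls(**known)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CompartmentSignal:
    """A dimensionless respiratory waveform for one compartment."""

    samples: np.ndarray
    fs: float
    compartment: str  # thorax | abdomen | sum
    t0: float = 0.0
    variance_explained: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiratory signal contains non-finite values")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ThresholdEstimate:
    """Eq.-style low-frequency threshold for one compartment."""

    f_mean: float
    f_std: float
    f_thresh: float
    compartment: str
    fallback: bool = False  # too few peaks -> floor used directly


@dataclass
class BandPassSpec:
    """Adaptive band-pass edges around the dominant respiratory frequency."""

    f_peak: float
    f_U: float
    f_L: float
    merged_low_threshold: float


@dataclass
class PeakSearch:
    """Welch-PSD peak search outcome."""

    f_peak: float
    freqs: np.ndarray
    psd: np.ndarray
    f_low: float
    f_max: float
    snr: float  # peak PSD over median in-band PSD


@dataclass
class BreathTable:
    """Detected breath events and per-breath RR for one compartment."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    rr_bpm: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.trough_times = np.asarray(self.trough_times, dtype=float)
        self.rr_bpm = np.asarray(self.rr_bpm, dtype=float)

    @property
    def n_breaths(self) -> int:
        return self.rr_bpm.size

    def median_rr(self) -> float:
        return float(np.median(self.rr_bpm)) if self.rr_bpm.size else float("nan")


@dataclass
class RRResult:
    """Full output of :func:`estimate_rr`."""

    breaths: dict  # compartment -> BreathTable
    medians: dict  # compartment -> float (bpm)
    preset: ActivityPreset
    flags: dict  # compartment -> list of str
    thresholds: dict  # compartment -> ThresholdEstimate
    merged_low_threshold: float
    bands: dict  # compartment -> BandPassSpec
    quality: str = "ok"  # "ok" | "low_snr"

    def breaths_frame(self) -> pd.DataFrame:
        """Long-format table ``compartment,breath_index,t_peak,rr_bpm``."""
        rows = []
        for comp, table in self.breaths.items():
            for i, rr in enumerate(table.rr_bpm):
                rows.append(
                    {
                        "compartment": comp,
                        "breath_index": i,
                        "t_peak": table.peak_times[i + 1],
                        "rr_bpm": rr,
                    }
                )
        return pd.DataFrame(rows, columns=["compartment", "breath_index", "t_peak", "rr_bpm"])

    def summary(self) -> str:
        payload = {
            "preset": self.preset.name,
            "quality": self.quality,
            "median_rr_bpm": {k: round(v, 3) if np.isfinite(v) else None
                              for k, v in self.medians.items()},
            "n_breaths": {k: t.n_breaths for k, t in self.breaths.items()},
            "merged_low_threshold_hz": round(self.merged_low_threshold, 4),
            "f_peak_hz": {k: round(b.f_peak, 4) for k, b in self.bands.items()},
            "band_hz": {k: [round(b.f_L, 4), round(b.f_U, 4)] for k, b in self.bands.items()},
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# pipeline stages


def remove_baseline(q: np.ndarray, window: int = 97) -> np.ndarray:
    """Subtract a centered moving-average baseline from each component.

    The window shrinks symmetrically at the edges (no padding), so no
    baseline is fabricated at the recording boundaries.  ``q`` is an
    ``(N, k)`` component array; the output has the same shape.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if window % 2 == 0:
        raise ConfigError("baseline window must be odd")
    if q.shape[0] <= window:
        raise InsufficientDataError(
            f"baseline stage: series of {q.shape[0]} samples needs > {window}"
        )
    baseline = (
        pd.DataFrame(q).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return q - baseline


def extract_pc1(
    components: np.ndarray,
    fs: float,
    compartment: str = "thorax",
    t0: float = 0.0,
) -> CompartmentSignal:
    """First principal component of the baseline-free quaternion components.

    The leading eigenvector of the 4×4 component covariance captures the
    coherent breathing rotation spread across the quaternion components; the
    projection onto it is the respiratory waveform.  The sign is fixed so the
    waveform correlates non-negatively with the first raw component (ties
    resolved toward a positive first loading) for cross-run determinism.
    """
    X = np.asarray(components, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("PCA stage: need at least 2 samples")
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 0):
        raise DegenerateInputError("PCA stage: all components constant")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Xc)[:, 0]
    loading = pca.components_[0]
    c = float(Xc[:, 0] @ scores)
    if c < 0 or (c == 0 and loading[0] < 0):
        scores = -scores
    return CompartmentSignal(
        samples=scores,
        fs=fs,
        compartment=compartment,
        t0=t0,
        variance_explained=float(pca.explained_variance_ratio_[0]),
    )


def threshold_from_stats(f_mean: float, f_std: float, preset: ActivityPreset) -> float:
    """Low-frequency threshold: ``max(f_thresh_min, f_mean − f_std)``."""
    return max(preset.f_thresh_min, f_mean - f_std)


def compute_threshold(
    sig: CompartmentSignal,
    preset: ActivityPreset,
    config: RRConfig | None = None,
) -> ThresholdEstimate:
    """Estimate the compartment's low-frequency threshold from peak spacing.

    The waveform is smoothed (Savitzky–Golay, order 3, window 31), its peaks
    located, and the mean and standard deviation of the inverse inter-peak
    intervals give ``f_mean`` and ``f_std``.  With fewer than 3 peaks the
    preset floor is used directly and the estimate is flagged as a fallback.
    """
    cfg = config or RRConfig()
    x = sig.samples
    if x.size < cfg.sg_window:
        raise InsufficientDataError(
            f"threshold stage: {x.size} samples < SG window {cfg.sg_window}"
        )
    sm = sps.savgol_filter(x, cfg.sg_window, cfg.sg_order)
    spread = float(np.std(sm))
    if spread > 0:
        peaks, _ = sps.find_peaks(sm, prominence=cfg.threshold_prominence_factor * spread)
    else:
        peaks = np.zeros(0, dtype=int)
    if peaks.size < 3:
        return ThresholdEstimate(
            f_mean=float("nan"),
            f_std=float("nan"),
            f_thresh=preset.f_thresh_min,
            compartment=sig.compartment,
            fallback=True,
        )
    inst_f = sig.fs / np.diff(peaks)  # inverse inter-peak intervals, Hz
    f_mean = float(np.mean(inst_f))
    f_std = float(np.std(inst_f))
    return ThresholdEstimate(
        f_mean=f_mean,
        f_std=f_std,
        f_thresh=threshold_from_stats(f_mean, f_std, preset),
        compartment=sig.compartment,
    )


def merge_thresholds(thorax: ThresholdEstimate, abdomen: ThresholdEstimate) -> float:
    """Shared low threshold: the minimum of the two compartment thresholds."""
    return min(thorax.f_thresh, abdomen.f_thresh)


def welch_find_peak(
    sig: CompartmentSignal,
    f_low: float,
    f_max: float,
    config: RRConfig | None = None,
) -> PeakSearch:
    """Dominant in-band frequency from the Welch PSD.

    Welch parameters: Hamming window, 300-sample segments, 50-sample overlap.
    Ties in the PSD maximum break toward the lower frequency.
    """
    cfg = config or RRConfig()
    x = sig.samples
    nyq = sig.fs / 2.0
    if not (0.0 <= f_low < f_max <= nyq):
        raise BandError(f"invalid search band [{f_low}, {f_max}] Hz (Nyquist {nyq} Hz)")
    if x.size < cfg.welch_nperseg:
        raise InsufficientDataError(
            f"spectrum stage: {x.size} samples < Welch window {cfg.welch_nperseg}"
        )
    freqs, psd = sps.welch(
        x,
        fs=sig.fs,
        window=sps.get_window("hamming", cfg.welch_nperseg),
        nperseg=cfg.welch_nperseg,
        noverlap=cfg.welch_noverlap,
        detrend="constant",
    )
    mask = (freqs >= f_low) & (freqs <= f_max)
    if not np.any(mask):
        raise BandError(f"empty search band [{f_low}, {f_max}] Hz at this resolution")
    band_f = freqs[mask]
    band_p = psd[mask]
    i = int(np.argmax(band_p))  # argmax returns the first (lowest-f) maximum
    med = float(np.median(band_p))
    snr = float(band_p[i] / med) if med > 0 else float("inf")
    return PeakSearch(
        f_peak=float(band_f[i]), freqs=freqs, psd=psd, f_low=f_low, f_max=f_max, snr=snr
    )


def design_bandpass(
    f_peak: float,
    merged_low_threshold: float,
    half_width: float = 0.04,
) -> BandPassSpec:
    """Adaptive band edges: ``f_U = f_peak + w``, ``f_L = max(f_m, f_peak − w)``."""
    if f_peak <= 0:
        raise BandError("f_peak must be positive")
    f_u = f_peak + half_width
    f_l = max(merged_low_threshold, f_peak - half_width)
    if f_l >= f_u:
        raise BandError(
            f"degenerate band: merged threshold {merged_low_threshold:.3f} Hz >= "
            f"upper edge {f_u:.3f} Hz"
        )
    return BandPassSpec(
        f_peak=f_peak, f_U=f_u, f_L=f_l, merged_low_threshold=merged_low_threshold
    )


def apply_bandpass(
    sig: CompartmentSignal,
    band: BandPassSpec,
    config: RRConfig | None = None,
) -> CompartmentSignal:
    """Zero-phase Butterworth band-pass between the adaptive edges.

    An order-2 design applied forward-backward (effective order 4) keeps the
    breath peak timing intact.  Edges are clamped to (1e−3, fs/2 − 1e−3) Hz.
    """
    cfg = config or RRConfig()
    nyq = sig.fs / 2.0
    f_l = max(band.f_L, 1e-3)
    f_u = min(band.f_U, nyq - 1e-3)
    if f_l >= f_u:
        raise BandError(f"band [{band.f_L}, {band.f_U}] Hz collapses inside (0, {nyq}) Hz")
    sos = sps.butter(cfg.butter_order, [f_l, f_u], btype="bandpass", fs=sig.fs, output="sos")
    y = sps.sosfiltfilt(sos, sig.samples)
    return CompartmentSignal(
        samples=y,
        fs=sig.fs,
        compartment=sig.compartment,
        t0=sig.t0,
        variance_explained=sig.variance_explained,
    )


def _tuned_sg_window(fs: float, f_peak: float, n: int, factor: float) -> int:
    """Odd Savitzky–Golay window near ``factor·fs/f_peak`` samples, >= 5, <= n."""
    w = int(round(factor * fs / f_peak))
    w = max(5, w | 1)
    if w > n:
        w = n if n % 2 else n - 1
    return w


def detect_breaths(
    sig: CompartmentSignal,
    f_peak: float,
    config: RRConfig | None = None,
) -> BreathTable:
    """Second smoothing pass plus maxima/minima detection tuned by ``f_peak``.

    The smoothing window, the minimum peak distance and the minimum
    prominence all scale with the dominant respiratory period so the detector
    keeps one maximum per breath: window ≈ 0.6·fs/f_peak samples, distance ≈
    0.5/f_peak seconds, prominence = 0.2 × the signal standard deviation.
    An oscillation-free signal yields an empty, flagged table.
    """
    cfg = config or RRConfig()
    if f_peak <= 0:
        raise BandError("f_peak must be positive")
    x = sig.samples
    if x.size < 5:
        return BreathTable([], [], [], flags=["no_breaths"])
    win = _tuned_sg_window(sig.fs, f_peak, x.size, cfg.tune_window_factor)
    sm = sps.savgol_filter(x, win, cfg.sg_order) if win > cfg.sg_order else x
    spread = float(np.std(sm))
    if spread == 0.0:
        return BreathTable([], [], [], flags=["no_breaths"])
    distance = max(1, int(round(cfg.tune_distance_factor / f_peak * sig.fs)))
    prominence = cfg.tune_prominence_factor * spread
    maxima, _ = sps.find_peaks(sm, distance=distance, prominence=prominence)
    minima, _ = sps.find_peaks(-sm, distance=distance, prominence=prominence)
    if maxima.size == 0:
        return BreathTable([], [], [], flags=["no_breaths"])
    peak_times = sig.t0 + maxima / sig.fs
    trough_times = sig.t0 + minima / sig.fs
    rr = 60.0 / np.diff(peak_times) if maxima.size > 1 else np.zeros(0)
    flags = [] if rr.size else ["single_breath"]
    return BreathTable(peak_times, trough_times, rr, flags=flags)


# ---------------------------------------------------------------------------
# full chain


def _stage(name, fn, *args, **kwargs):
    """Run a stage, annotating pipeline errors with the stage name."""
    try:
        return fn(*args, **kwargs)
    except (InsufficientDataError, BandError, DegenerateInputError) as e:
        msg = str(e)
        if not msg.startswith(name):
            e.args = (f"{name}: {msg}",)
        raise


def respiratory_signal(
    unit: QuaternionSeries,
    ref: QuaternionSeries,
    fs: float,
    compartment: str,
    config: RRConfig | None = None,
) -> CompartmentSignal:
    """Referencing + baseline removal + PCA for one compartment."""
    cfg = config or RRConfig()
    rel = _stage("referencing", relative_series, unit, ref)
    comps = _stage("baseline", remove_baseline, rel.q, cfg.baseline_window)
    return _stage("pca", extract_pc1, comps, fs, compartment, float(unit.t[0]))


def estimate_rr(
    rec: Recording,
    preset: ActivityPreset | str,
    config: RRConfig | None = None,
) -> RRResult:
    """Run the full RR chain on a recording.

    Returns breath tables and median RR for the thoracic compartment, the
    abdominal compartment and their sum (the sum of the two band-passed
    waveforms, processed with the thoracic band and peak frequency).  A
    ``low_snr`` quality is reported when no compartment shows a PSD peak at
    least ``snr_floor`` times the median in-band power — the regime in which
    breath extraction is untrustworthy (e.g. stair climbing).
    """
    cfg = config or RRConfig()
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
        preset = PRESETS[preset]
    fs = rec.fs

    signals = {
        comp: respiratory_signal(rec.series(comp), rec.reference, fs, comp, cfg)
        for comp in ("thorax", "abdomen")
    }
    thresholds = {
        comp: _stage("threshold", compute_threshold, sig, preset, cfg)
        for comp, sig in signals.items()
    }
    merged = merge_thresholds(thresholds["thorax"], thresholds["abdomen"])

    breaths: dict = {}
    bands: dict = {}
    flags: dict = {comp: [] for comp in ("thorax", "abdomen", "sum")}
    filtered: dict = {}
    low_snr: dict = {}
    for comp, sig in signals.items():
        low = merged if cfg.merged_threshold_mode == "merged" else thresholds[comp].f_thresh
        search = _stage("spectrum", welch_find_peak, sig, low, preset.f_search_max, cfg)
        band = _stage("band design", design_bandpass, search.f_peak, low, cfg.band_half_width)
        filt = _stage("band-pass", apply_bandpass, sig, band, cfg)
        table = detect_breaths(filt, band.f_peak, cfg)
        if thresholds[comp].fallback:
            table.flags.append("threshold_fallback")
        low_snr[comp] = search.snr < cfg.snr_floor
        if low_snr[comp]:
            table.flags.append("low_snr")
        bands[comp] = band
        breaths[comp] = table
        flags[comp] = list(table.flags)
        filtered[comp] = filt

    # sum of the two filtered compartment waveforms, thoracic tuning reused
    sum_sig = CompartmentSignal(
        samples=filtered["thorax"].samples + filtered["abdomen"].samples,
        fs=fs,
        compartment="sum",
        t0=filtered["thorax"].t0,
    )
    sum_table = detect_breaths(sum_sig, bands["thorax"].f_peak, cfg)
    breaths["sum"] = sum_table
    bands["sum"] = bands["thorax"]
    flags["sum"] = list(sum_table.flags)

    medians = {comp: table.median_rr() for comp, table in breaths.items()}
    quality = "low_snr" if all(low_snr.values()) else "ok"
    return RRResult(
        breaths=breaths,
        medians=medians,
        preset=preset,
        flags=flags,
        thresholds=thresholds,
        merged_low_threshold=merged,
        bands=bands,
        quality=quality,
    )


def write_rr_result(result: RRResult, csv_path, summary_path=None) -> None:
    """Export the breath table as CSV and (optionally) the JSON summary."""
    result.breaths_frame().to_csv(csv_path, index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write(result.summary() + "\n")
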