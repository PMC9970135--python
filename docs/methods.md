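# Methods

This note records the models behind `quatresp`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Signal model

Each sensor unit reports its orientation with respect to a fixed Earth frame
as a unit quaternion at 10 Hz (the device fuses 9-axis data at 40 Hz and
transmits every fourth sample, with a one-byte per-transmission counter that
wraps modulo 256).  Writing `q_th`, `q_ab`, `q_ref` for the thoracic,
abdominal and lower-back orientations, the chest-wall units are modelled as

    q_th(t) = δ_th(t) ⊗ q_trunk(t) ⊗ n_th(t)
    q_ab(t) = δ_ab(t) ⊗ q_trunk(t) ⊗ n_ab(t)
    q_ref(t) =          q_trunk(t) ⊗ n_ref(t)

where `q_trunk` is the shared trunk orientation (posture plus whole-body
motion), `δ` are small breathing rotations and `n` are small sensor
perturbations.  The relative orientation `q_th ⊗ q_ref*` therefore cancels
`q_trunk` exactly up to the (small, incoherent) noise terms, which is the
premise of the whole chain: breathing survives referencing, gait does not.

Quaternion conventions: Hamilton product, scalar-first `(w, x, y, z)`
component order.  Every product chain is renormalized (tolerance 1e−6 on
ingest, 1e−9 internally), and relative series are sign-canonicalized to
`w ≥ 0` so the ±q double cover cannot inject steps into the baseline.

## RR chain parameters

All defaults live in `quatresp.rr.RRConfig` and are overridable from the
CLI via a YAML file:

| parameter | default | unit | role |
| --- | --- | --- | --- |
| `baseline_window` | 97 | samples | centered moving average subtracted per component |
| `sg_window`, `sg_order` | 31, 3 | samples, – | first smoothing pass before peak statistics |
| `welch_nperseg`, `welch_noverlap` | 300, 50 | samples | Welch PSD segmentation (Hamming) |
| `band_half_width` | 0.04 | Hz | adaptive band edges around `f_peak` |
| `tune_window_factor` | 0.6 | – | second SG window ≈ 0.6·fs/f_peak (odd, ≥ 5) |
| `tune_distance_factor` | 0.5 | – | min peak distance ≈ 0.5/f_peak seconds |
| `tune_prominence_factor` | 0.2 | – | min prominence = 0.2 × signal std |
| `threshold_prominence_factor` | 0.25 | – | peak floor when estimating `f_mean`, `f_std` |
| `snr_floor` | 3.0 | – | PSD peak / median in-band PSD below → `low_snr` |
| `butter_order` | 2 | – | Butterworth order, applied forward-backward |

Activity presets: static (floor 0.05 Hz, ceiling 1.0 Hz), walking and
cycling (0.2, 0.75), running (0.4, 1.4).  In breaths/min these bounds span
3–60 (static) up to 24–84 (running).

Choices that were genuinely open:

* **Filter family.** No filter family is prescribed for the adaptive
  band-pass; an order-2 Butterworth run forward-backward (`sosfiltfilt`,
  effective order 4) was chosen because zero phase preserves breath-peak
  timing, which the breath-by-breath RR definition depends on.  Edges are
  clamped to (1e−3, fs/2 − 1e−3) Hz.
* **Peak-tuning map.** The exact dependence of the second smoothing window,
  minimum peak distance and prominence on `f_peak` is not public; the three
  factors above are stand-ins scaled to the breathing period (window ≈ 0.6
  periods, distance ≈ half a period) and are exposed as config keys.
* **Per-compartment `f_peak`.** The peak search and band construction run
  per compartment with the shared merged low threshold; the sum signal
  reuses the thoracic band and peak.  `merged_threshold_mode =
  "per_compartment"` switches `f_L` to each compartment's own threshold.
* **Threshold peak floor.** When estimating `f_mean`/`f_std` from inter-peak
  intervals, peaks must exceed 0.25 × the smoothed-signal standard deviation
  in prominence; without a floor, sensor noise generates spurious peaks that
  inflate the threshold above the true breathing frequency.  With fewer than
  3 peaks the preset floor is used and the estimate is flagged.
* **PCA sign.** PC1 is oriented to correlate non-negatively with the first
  raw component (ties → positive first loading), for bit-identical results
  across runs and platforms.
* **Moving-average edges.** The 97-sample window shrinks symmetrically at
  the recording edges instead of padding, so no baseline is fabricated at
  the boundaries.
* **Breath definition.** RR derives from consecutive *maxima* intervals;
  minima are detected and stored but do not enter the rate.
* **Low-SNR rule.** A compartment is flagged when its PSD peak is below 3×
  the median in-band PSD; the recording-level quality is `low_snr` only when
  *both* compartments are flagged (one clean compartment still supports an
  estimate).  This models the stair-climbing regime in which the method is
  not trustworthy.

## Ingest

Counter gaps ≤ 10 samples (1 s) are filled by component-wise linear
interpolation plus renormalization — indistinguishable from spherical
interpolation below ~5° of rotation per 0.1 s step, which is far above any
physiological rate of change at 10 Hz.  Longer gaps raise an error naming
the interval rather than silently interpolating through them.  When no
manual analysis window is given, the first 30 s are trimmed to drop the
orientation-filter transient; manual start/end selection stays available.

## Activity recognition

Standardization is fitted on the *whole* corpus before the split, matching
the published processing order; this leaks test statistics into training
and a `fit_on_train` mode is provided for leakage-free evaluation.
Features are computed per channel; with frequency features on, each channel
contributes 15 features (8 time + 7 frequency), giving 60 columns for one
unit and 180 for three; the three-unit default is time-only (96 columns).
Features enter the classifiers at their natural scale — there is no second,
feature-level standardization.  Macro averaging is used for precision,
recall and F1 (robust to residual class imbalance); the IQR uses
linear-interpolation quartiles; kurtosis is Fisher-style; FFT features
exclude the zero-frequency bin; degenerate constant windows get zero
kurtosis/skewness.  Class labels are encoded in lexicographic order.  The
single-unit configuration keeps the class imbalance; the three-unit
configuration balances by seeded downsampling to the smallest class.  The
80/20 split is a plain seeded shuffle (seed 42), not stratified.

## The synthetic generator

The generator emulates the twelve-task study protocol (seven static
postures, five dynamic activities, 5 min each) with:

* distinct trunk base orientations per task (≥ 8° apart in at least one
  axis), with per-subject jitter of ±3°;
* shared motion: roll at the gait cadence plus pitch at twice the cadence
  (walking 1.6/1.8 Hz for the two speeds, running 2.8 Hz, cycling 1.5 Hz,
  stairs 1.4 Hz; static postures get a 0.3 Hz, ~0.5° sway).  The two
  walking speeds deliberately straddle a 1.7 Hz mean so the merged
  "walking" class is not a single point;
* breathing: a sinusoidal rotation about a fixed per-compartment axis, 2° on
  the dominant compartment and 0.8° on the other — thorax dominant upright,
  abdomen dominant when horizontal, reproducing the known posture dependence
  of chest-wall compartment contributions;
* sensor noise: independent per-sample rotations, angle ~ N(0, 0.15°);
* stairs: 3× noise *plus* an independent per-unit band-limited (< 0.8 Hz)
  wobble of 5° about a fixed random axis.  White noise alone cannot create
  the low-SNR regime (its power spreads over the whole spectrum and leaves
  the Welch peak towering over the in-band median); the non-shared
  low-frequency wobble is what actually defeats referencing during stair
  climbing, and with it the `low_snr` flag trips in 18 of 20 default seeds;
* dropouts: each transmission lost independently with probability 0.02 by
  default, visible to readers only through counter jumps.  Ground truth is
  a sidecar file, never part of the quaternion log.

Amplitudes are free parameters (no quantitative chest-wall rotation
amplitudes are published); 2°/0.8° give a realistic signal-to-noise ratio
against 0.15° sensor noise.

What the generator does **not** emulate: biomechanically detailed gait,
magnetometer disturbance, sensor drift, respiratory-rate variability within
a task (supported via `rr_true` traces but not exercised by default),
breathing–gait entrainment, and inter-breath amplitude variation.  Passing
tests therefore demonstrate that the chain is implemented correctly and
recovers known rates under realistic noise, motion and dropout — not that
it reaches any particular accuracy on human data.

## Benchmark problem sizes

The RR grid uses 20 five-minute recordings (five per preset, rates 12–50
breaths/min, seeds 1–20 at base seed 1), each round-tripped through the
on-disk log format before estimation; it completes in seconds.  The HAR
benchmark uses 5 synthetic subjects × 12 tasks (60 recordings, ~780 windows
after the 30 s trim) with seed 7.  Both sizes mirror the scale of the
original protocol (12 tasks × 5 min per subject) while staying desk-scale.

## Known limitations

* Breath timing is quantized to the 10 Hz grid, so individual breath rates
  at high RR step coarsely (at 50 breaths/min one sample is ~4 breaths/min);
  medians over a recording are much finer.
* The adaptive band is only as good as `f_peak`; when the merged threshold
  rises to the true breathing frequency (very regular breathing), the band's
  lower edge can sit exactly on it, attenuating but not losing the peak.
* `estimate_rr` assumes a single dominant rate per analysis window; a
  sliding-window mode for rate tracking is future work.
* Stair climbing is detected as unreliable, not fixed: the flag is the
  product, matching how such recordings must be excluded downstream.
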