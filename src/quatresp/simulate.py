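"""Synthetic three-unit quaternion recordings with known ground truth.

The generator emulates the wearable's output during the study protocol:
twelve five-minute tasks (seven static postures, five dynamic activities).
Each task is rendered as

* a task-specific base orientation of the trunk (sitting reclined, supine,
  cycling lean, ...) shared by all three units;
* an activity motion oscillation shared by all three units — roll at the gait
  cadence plus pitch at twice the cadence for dynamic tasks, a slow small
  postural sway for static ones;
* a breathing micro-rotation applied only to the thoracic and abdominal
  units: a sinusoidal rotation angle at ``rr_true/60`` Hz about a fixed
  per-compartment axis, with the larger amplitude on the thorax in upright
  postures and on the abdomen in horizontal ones;
* independent small-angle sensor noise per unit per sample;
* counter-gap dropouts at a configurable rate, emulating lost transmissions.

Ground truth is emitted as a sidecar table (``t,rr_true_bpm,activity``) and
never embedded in the quaternion log, so the estimation pipeline cannot peek.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Recording
from .quaternions import QuaternionSeries, from_axis_angle, multiply, normalize

STATIC_TASKS = (
    "sitting_support",
    "sitting_no_support",
    "supine",
    "prone",
    "lying_left",
    "lying_right",
    "standing",
)
DYNAMIC_TASKS = ("walking_4kmh", "walking_6kmh", "running", "stairs", "cycling")
ALL_TASKS = STATIC_TASKS + DYNAMIC_TASKS

#: tasks in which the abdominal compartment dominates the breathing motion
HORIZONTAL_TASKS = frozenset({"supine", "prone", "lying_left", "lying_right"})

#: trunk base orientation per task: intrinsic (roll, pitch, yaw) in degrees.
#: Values are separated by >= 8 degrees in at least one axis so postures are
#: distinguishable from orientation alone, as they are for the real device.
TASK_ORIENTATION_DEG = {
    "sitting_support": (0.0, 15.0, 0.0),
    "sitting_no_support": (0.0, 25.0, 0.0),
    "supine": (0.0, 80.0, 0.0),
    "prone": (0.0, -80.0, 0.0),
    "lying_left": (75.0, 0.0, 0.0),
    "lying_right": (-75.0, 0.0, 0.0),
    "standing": (0.0, 0.0, 0.0),
    "walking_4kmh": (0.0, 5.0, 40.0),
    "walking_6kmh": (0.0, 8.0, 60.0),
    "running": (0.0, 18.0, 120.0),
    "stairs": (0.0, 35.0, -160.0),
    "cycling": (0.0, 55.0, -60.0),
}

#: per-task motion: (cadence Hz, roll amplitude deg, pitch amplitude deg,
#: noise multiplier).  Stairs get triple noise and, below, an independent
#: per-unit low-frequency wobble, reproducing the low signal-to-noise regime
#: in which breath extraction must be flagged.
TASK_MOTION = {
    "sitting_support": (0.3, 0.5, 0.25, 1.0),
    "sitting_no_support": (0.3, 0.5, 0.25, 1.0),
    "supine": (0.3, 0.3, 0.15, 1.0),
    "prone": (0.3, 0.3, 0.15, 1.0),
    "lying_left": (0.3, 0.3, 0.15, 1.0),
    "lying_right": (0.3, 0.3, 0.15, 1.0),
    "standing": (0.3, 0.5, 0.25, 1.0),
    "walking_4kmh": (1.6, 6.0, 3.0, 1.0),
    "walking_6kmh": (1.8, 9.0, 4.5, 1.0),
    "running": (2.8, 12.0, 6.0, 1.0),
    "stairs": (1.4, 7.0, 3.5, 3.0),
    "cycling": (1.5, 4.0, 2.0, 1.0),
}

#: independent per-unit low-frequency wobble amplitude (degrees): motion of a
#: unit relative to the trunk that the reference cannot cancel.  Stair
#: climbing jolts the chest and the lower back differently at every step,
#: which is what makes its respiratory extraction untrustworthy.
TASK_ARTIFACT_DEG = {**{t: 0.0 for t in ALL_TASKS}, "stairs": 5.0}

#: typical true-RR range per task, breaths/min, used by the corpus generator
TASK_RR_RANGE = {
    **{t: (10.0, 18.0) for t in STATIC_TASKS},
    "walking_4kmh": (18.0, 26.0),
    "walking_6kmh": (20.0, 28.0),
    "running": (32.0, 42.0),
    "stairs": (20.0, 28.0),
    "cycling": (16.0, 24.0),
}

_AX_X = np.array([1.0, 0.0, 0.0])
_AX_Y = np.array([0.0, 1.0, 0.0])
_AX_Z = np.array([0.0, 0.0, 1.0])
#: fixed breathing rotation axes (pitch-like, slightly tilted for the abdomen)
THORAX_BREATH_AXIS = _AX_Y
ABDOMEN_BREATH_AXIS = normalize(np.array([0.0, np.cos(np.radians(15)), np.sin(np.radians(15))]))


@dataclass
class Scenario:
    """One synthetic task recording, fully specified.

    Amplitudes are rotation angles in degrees.  ``thorax_amp_deg`` /
    ``abdomen_amp_deg`` default to the posture rule: 2° on the dominant
    compartment (thorax when upright, abdomen when horizontal) and 0.8° on
    the other.  ``rr_true`` may be a scalar or a per-sample trace.
    """

    activity: str = "sitting_no_support"
    duration: float = 300.0  # seconds; protocol tasks last 5 min
    rr_true: float | np.ndarray = 15.0  # breaths/min
    fs: float = 10.0
    thorax_amp_deg: float | None = None
    abdomen_amp_deg: float | None = None
    cadence_hz: float | None = None
    motion_roll_deg: float | None = None
    motion_pitch_deg: float | None = None
    noise_deg: float = 0.15
    artifact_deg: float | None = None  # per-unit in-band wobble; task default
    dropout_rate: float = 0.02
    orient_jitter_deg: tuple = (0.0, 0.0, 0.0)
    seed: int = 0
    subject_id: str = "sim"

    def __post_init__(self):
        if self.activity not in ALL_TASKS:
            raise ValidationError(f"unknown activity {self.activity!r}; valid: {ALL_TASKS}")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        rr = np.atleast_1d(np.asarray(self.rr_true, dtype=float))
        if np.any(rr < 5.0) or np.any(rr > 60.0):
            raise ValidationError("rr_true must lie in [5, 60] breaths/min")
        if not (0.0 <= self.dropout_rate < 0.2):
            raise ValidationError("dropout_rate must lie in [0, 0.2)")
        if self.noise_deg < 0:
            raise ValidationError("noise_deg must be non-negative")

    def breathing_amplitudes(self) -> tuple[float, float]:
        """(thorax, abdomen) amplitudes in degrees after the posture rule."""
        dominant, other = 2.0, 0.8
        if self.activity in HORIZONTAL_TASKS:
            th = other if self.thorax_amp_deg is None else self.thorax_amp_deg
            ab = dominant if self.abdomen_amp_deg is None else self.abdomen_amp_deg
        else:
            th = dominant if self.thorax_amp_deg is None else self.thorax_amp_deg
            ab = other if self.abdomen_amp_deg is None else self.abdomen_amp_deg
        return th, ab


def _euler_quat(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Intrinsic z-y'-x'' (yaw, pitch, roll) composition as a unit quaternion."""
    qz = from_axis_angle(_AX_Z, np.radians(yaw_deg))
    qy = from_axis_angle(_AX_Y, np.radians(pitch_deg))
    qx = from_axis_angle(_AX_X, np.radians(roll_deg))
    return multiply(multiply(qz, qy), qx)


def _noise_quats(rng: np.random.Generator, n: int, std_deg: float) -> np.ndarray:
    """Independent small random rotations, angle ~ N(0, std) about random axes."""
    if std_deg == 0.0:
        return np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, np.radians(std_deg), size=n)
    return from_axis_angle(axes, angles)


def _artifact_quats(
    rng: np.random.Generator, n: int, fs: float, amp_deg: float
) -> np.ndarray:
    """Band-limited (< ~0.8 Hz) per-unit wobble about a fixed random axis.

    Unlike the white sensor noise this lands inside the respiratory search
    band and cannot be cancelled by referencing, so it degrades the PSD peak
    prominence the way real non-shared body motion does.
    """
    if amp_deg == 0.0:
        return np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    from scipy import signal as sps

    sos = sps.butter(2, 0.8, btype="lowpass", fs=fs, output="sos")
    angle = sps.sosfilt(sos, rng.normal(size=n))
    angle = angle / max(np.std(angle), 1e-12) * np.radians(amp_deg)
    axis = rng.normal(size=3)
    return from_axis_angle(axis / np.linalg.norm(axis), angle)


def simulate_recording(s: Scenario) -> tuple[Recording, pd.DataFrame]:
    """Render a scenario into an aligned recording plus its truth sidecar.

    The returned recording is gap-free; the sample indices elected for
    dropout are stored in ``rec.meta['dropout']`` and applied by
    :func:`quatresp.io.write_log`, so the on-disk log carries the counter
    gaps while in-memory processing stays exact.
    """
    rng = np.random.default_rng(s.seed)
    n = int(round(s.duration * s.fs))
    t = np.arange(n) / s.fs

    rr = np.broadcast_to(np.atleast_1d(np.asarray(s.rr_true, dtype=float)), (n,))
    # integrated phase supports slowly varying rr traces
    phase = 2.0 * np.pi * np.cumsum(rr / 60.0) / s.fs

    roll0, pitch0, yaw0 = (
        base + jit for base, jit in zip(TASK_ORIENTATION_DEG[s.activity], s.orient_jitter_deg)
    )
    q0 = _euler_quat(roll0, pitch0, yaw0)

    cadence, roll_amp, pitch_amp, noise_mult = TASK_MOTION[s.activity]
    cadence = s.cadence_hz if s.cadence_hz is not None else cadence
    roll_amp = s.motion_roll_deg if s.motion_roll_deg is not None else roll_amp
    pitch_amp = s.motion_pitch_deg if s.motion_pitch_deg is not None else pitch_amp
    q_motion = multiply(
        from_axis_angle(_AX_X, np.radians(roll_amp) * np.sin(2 * np.pi * cadence * t)),
        from_axis_angle(_AX_Y, np.radians(pitch_amp) * np.sin(4 * np.pi * cadence * t)),
    )
    ref_clean = multiply(q0, q_motion)

    th_amp, ab_amp = s.breathing_amplitudes()
    breath_th = from_axis_angle(THORAX_BREATH_AXIS, np.radians(th_amp) * np.sin(phase))
    breath_ab = from_axis_angle(ABDOMEN_BREATH_AXIS, np.radians(ab_amp) * np.sin(phase))

    noise_std = s.noise_deg * noise_mult
    artifact = s.artifact_deg if s.artifact_deg is not None else TASK_ARTIFACT_DEG[s.activity]
    wobble = {u: _artifact_quats(rng, n, s.fs, artifact)
              for u in ("thorax", "abdomen", "reference")}
    streams = {
        "reference": multiply(
            multiply(wobble["reference"], ref_clean), _noise_quats(rng, n, noise_std)
        ),
        "thorax": multiply(
            multiply(breath_th, multiply(wobble["thorax"], ref_clean)),
            _noise_quats(rng, n, noise_std),
        ),
        "abdomen": multiply(
            multiply(breath_ab, multiply(wobble["abdomen"], ref_clean)),
            _noise_quats(rng, n, noise_std),
        ),
    }

    dropout = {}
    for unit in ("thorax", "abdomen", "reference"):
        if s.dropout_rate > 0:
            lost = np.nonzero(rng.random(n) < s.dropout_rate)[0]
            # keep the endpoints so the grid anchors survive
            dropout[unit] = lost[(lost > 0) & (lost < n - 1)]
        else:
            dropout[unit] = np.zeros(0, dtype=int)

    series = {
        u: QuaternionSeries(t, normalize(q), u, {"synthetic": True})
        for u, q in streams.items()
    }
    rec = Recording(
        thorax=series["thorax"],
        abdomen=series["abdomen"],
        reference=series["reference"],
        fs=s.fs,
        label=s.activity,
        subject_id=s.subject_id,
        meta={"dropout": dropout, "scenario_seed": s.seed},
    )
    truth = pd.DataFrame({"t": t, "rr_true_bpm": rr, "activity": s.activity})
    return rec, truth


def default_catalogue(duration: float = 300.0) -> list[Scenario]:
    """One template scenario per protocol task."""
    return [Scenario(activity=task, duration=duration) for task in ALL_TASKS]


def simulate_har_corpus(
    catalogue: list[Scenario] | None = None,
    subjects: int = 5,
    seed: int = 7,
) -> list[Recording]:
    """Labeled corpus: one recording per task per synthetic subject.

    Each subject draws seeded jitter — base-orientation offsets (±3°),
    breathing/motion amplitude scaling (×0.85–1.15), cadence offsets
    (±0.1 Hz) and a task-typical true RR — so no two subjects are identical
    while classes remain separable, mimicking inter-subject variability.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if not catalogue:
        raise ValidationError("scenario catalogue is empty")
    if subjects < 1:
        raise ValidationError("subjects must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[Recording] = []
    for si in range(subjects):
        subject_id = f"S{si:02d}"
        for template in catalogue:
            task = template.activity
            lo, hi = TASK_RR_RANGE[task]
            amp_scale = rng.uniform(0.85, 1.15)
            th_amp, ab_amp = template.breathing_amplitudes()
            cad, roll_amp, pitch_amp, _ = TASK_MOTION[task]
            s = replace(
                template,
                rr_true=float(rng.uniform(lo, hi)),
                thorax_amp_deg=th_amp * amp_scale,
                abdomen_amp_deg=ab_amp * amp_scale,
                cadence_hz=cad + float(rng.uniform(-0.1, 0.1)),
                motion_roll_deg=roll_amp * float(rng.uniform(0.9, 1.1)),
                motion_pitch_deg=pitch_amp * float(rng.uniform(0.9, 1.1)),
                orient_jitter_deg=tuple(rng.uniform(-3.0, 3.0, size=3)),
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=subject_id,
            )
            rec, _ = simulate_recording(s)
            corpus.append(rec)
    return corpus
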