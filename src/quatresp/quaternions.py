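"""Quaternion algebra for chest-wall orientation streams.

All quaternions are scalar-first ``(w, x, y, z)`` arrays under the Hamilton
product convention.  Orientation streams are ``(N, 4)`` float arrays wrapped
in :class:`QuaternionSeries` together with their timestamps and the body
location of the sensor unit that produced them.

The central operation is :func:`relative_series`: expressing the thoracic or
abdominal orientation in the frame of a reference unit worn on the lower
back, ``q_rel = q_unit ⊗ q_ref*``.  Because the reference unit moves with the
trunk but does not breathe, the shared trunk motion cancels algebraically and
only the breathing micro-rotation survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError

#: unit-norm tolerance applied to freshly ingested data
INGEST_NORM_TOL = 1e-6
#: unit-norm tolerance maintained through internal product chains
INTERNAL_NORM_TOL = 1e-9

UNIT_IDS = ("thorax", "abdomen", "reference")

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q`` scaled to unit norm along the last axis."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate ``(w, -x, -y, -z)``; inverts a unit rotation."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (scalar-first, broadcasting on leading axes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Resolve the ±q double cover by enforcing ``w >= 0``.

    Without a canonical sign, consecutive samples of a slowly varying
    orientation can flip between q and −q and inject spurious steps into the
    baseline that later stages would mistake for motion.
    """
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def from_axis_angle(axis, angle) -> np.ndarray:
    """Unit quaternion rotating by ``angle`` (radians) about ``axis``.

    ``angle`` may be an array; the axis is normalized and broadcast.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    half = 0.5 * np.asarray(angle, dtype=float)[..., None]
    return np.concatenate(
        [np.cos(half), np.sin(half) * np.broadcast_to(axis, half.shape[:-1] + (3,))],
        axis=-1,
    )


def rotation_angle(q: np.ndarray) -> np.ndarray:
    """Total rotation angle (radians, in [0, pi]) encoded by unit quaternion(s)."""
    w = np.clip(np.abs(np.asarray(q, dtype=float)[..., 0]), -1.0, 1.0)
    return 2.0 * np.arccos(w)


@dataclass
class QuaternionSeries:
    """Timestamped unit-norm quaternion sequence from one sensor unit.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing (nominally 10 Hz).
    q : array, shape (N, 4)
        Scalar-first quaternion components.
    unit_id : str
        One of ``thorax``, ``abdomen``, ``reference``.
    """

    t: np.ndarray
    q: np.ndarray
    unit_id: str = "reference"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError(f"quaternion array must be (N, 4), got {self.q.shape}")
        if self.t.shape[0] != self.q.shape[0]:
            raise ValueError("timestamp / quaternion length mismatch")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.q.shape[0]

    @property
    def duration(self) -> float:
        """Span between first and last sample, seconds."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def normalized(self, tol: float = INGEST_NORM_TOL) -> "QuaternionSeries":
        """Return a copy with quaternions renormalized to unit length."""
        return QuaternionSeries(self.t.copy(), normalize(self.q), self.unit_id, dict(self.meta))

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=1)


def relative_series(
    unit: QuaternionSeries,
    ref: QuaternionSeries,
    time_atol: float = 1e-9,
) -> QuaternionSeries:
    """Orientation of ``unit`` expressed in the frame of ``ref``.

    Computes the element-wise Hamilton product ``q_unit ⊗ q_ref*``.  When the
    reference stream carries exactly the shared trunk motion, the output is
    the residual (breathing) rotation alone.  The result is renormalized and
    sign-canonicalized (``w >= 0``).
    """
    if len(unit) != len(ref):
        raise AlignmentError(
            f"series length mismatch: {unit.unit_id} has {len(unit)} samples, "
            f"{ref.unit_id} has {len(ref)}"
        )
    if not np.allclose(unit.t, ref.t, rtol=0.0, atol=time_atol):
        raise AlignmentError(f"timestamp mismatch between {unit.unit_id} and {ref.unit_id}")
    rel = multiply(unit.q, conjugate(ref.q))
    rel = canonicalize(normalize(rel))
    return QuaternionSeries(unit.t.copy(), rel, unit.unit_id, {"referenced": True})
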