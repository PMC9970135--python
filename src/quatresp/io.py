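"""Quaternion log ingest: parsing, gap filling, alignment, trimming.

Log dialect
-----------
A recording is a UTF-8 CSV file with the exact header::

    subject_id,unit_id,counter,t,qw,qx,qy,qz

with one row per transmitted sample, '.' decimal separator, ``unit_id`` one
of ``thorax`` / ``abdomen`` / ``reference``, ``t`` in seconds and a per-unit
transmission counter that wraps modulo 256 (the device increments a one-byte
counter once per transmitted quaternion, i.e. every fourth 40 Hz fusion
update, so consecutive rows of one unit differ by 1 modulo 256).  Dropped
transmissions therefore show up as counter jumps, which is how gaps are
detected and re-filled here.

A ground-truth sidecar (written by the simulator, never read by the RR
pipeline) is a CSV with header ``t,rr_true_bpm,activity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, BoundsError, FormatError, GapError
from .quaternions import INGEST_NORM_TOL, QuaternionSeries, normalize

CSV_COLUMNS = ["subject_id", "unit_id", "counter", "t", "qw", "qx", "qy", "qz"]
UNIT_IDS = ("thorax", "abdomen", "reference")
COUNTER_WRAP = 256
DEFAULT_FS = 10.0
DEFAULT_MAX_GAP = 10  # samples (1 s at 10 Hz)
DEFAULT_TRIM_S = 30.0  # initial transient removed when no manual window given
_FLOAT_FMT = "%.10g"


@dataclass
class RawLog:
    """Per-unit raw record tables straight from :func:`parse_log`."""

    subject_id: str
    units: dict  # unit_id -> DataFrame[counter, t, qw, qx, qy, qz]

    def counts(self) -> dict:
        return {u: len(df) for u, df in self.units.items()}


@dataclass
class Recording:
    """Aligned three-unit quaternion recording.

    All three series share length and timestamps; ``fs`` is the nominal
    sampling rate (10 Hz for the wearable described in the log dialect).
    """

    thorax: QuaternionSeries
    abdomen: QuaternionSeries
    reference: QuaternionSeries
    fs: float = DEFAULT_FS
    label: str | None = None
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.thorax)
        if len(self.abdomen) != n or len(self.reference) != n:
            raise AlignmentError("the three unit series must have equal length")
        if n and not (
            np.allclose(self.thorax.t, self.reference.t)
            and np.allclose(self.abdomen.t, self.reference.t)
        ):
            raise AlignmentError("the three unit series must share timestamps")

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count over fs)."""
        return len(self) / self.fs

    def series(self, unit_id: str) -> QuaternionSeries:
        if unit_id not in UNIT_IDS:
            raise KeyError(unit_id)
        return getattr(self, unit_id)


def parse_log(path) -> RawLog:
    """Parse a quaternion log file into per-unit record tables.

    Records are grouped by ``unit_id`` preserving file order; timestamps must
    be monotone within each unit and unit ids must belong to the dialect.
    """
    df = pd.read_csv(path)
    if list(df.columns) != CSV_COLUMNS:
        raise FormatError(
            f"unexpected header {list(df.columns)!r}; expected {CSV_COLUMNS!r}"
        )
    unknown = sorted(set(df["unit_id"].astype(str)) - set(UNIT_IDS))
    if unknown:
        raise FormatError(f"unknown unit_id value(s): {unknown}")
    subjects = df["subject_id"].astype(str).unique()
    if len(subjects) > 1:
        raise FormatError(f"log mixes subjects: {sorted(subjects)}")
    units = {}
    for unit_id, group in df.groupby("unit_id", sort=False):
        t = group["t"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise FormatError(f"non-monotone timestamps for unit {unit_id!r}")
        units[str(unit_id)] = group[["counter", "t", "qw", "qx", "qy", "qz"]].reset_index(
            drop=True
        )
    return RawLog(subject_id=str(subjects[0]) if len(subjects) else "", units=units)


def gap_lengths(counter: np.ndarray, wrap: int = COUNTER_WRAP) -> np.ndarray:
    """Missing-sample count between each pair of consecutive records.

    The counter wraps modulo ``wrap``; a jump of k+1 means k lost samples.
    """
    counter = np.asarray(counter, dtype=np.int64)
    if counter.size < 2:
        return np.zeros(0, dtype=np.int64)
    return (np.diff(counter) - 1) % wrap


def fill_missing(
    records: pd.DataFrame,
    unit_id: str,
    fs: float = DEFAULT_FS,
    max_gap: int = DEFAULT_MAX_GAP,
    wrap: int = COUNTER_WRAP,
) -> QuaternionSeries:
    """Rebuild an equispaced unit-norm series from raw records with gaps.

    Gap positions are inferred from the transmission counter; gaps of at most
    ``max_gap`` samples are filled by component-wise linear interpolation
    followed by renormalization.  Filled sample indices are recorded in the
    returned series' ``meta['filled']``.

    Raises
    ------
    GapError
        If any gap exceeds ``max_gap`` samples (the interval is named).
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    counter = records["counter"].to_numpy(dtype=np.int64)
    t = records["t"].to_numpy(dtype=float)
    gaps = gap_lengths(counter, wrap)
    too_long = np.nonzero(gaps > max_gap)[0]
    if too_long.size:
        i = int(too_long[0])
        raise GapError(
            f"unit {unit_id!r}: gap of {int(gaps[i])} samples between "
            f"t={t[i]:.3f}s and t={t[i + 1]:.3f}s exceeds max_gap={max_gap}"
        )
    # position of each observed record on the ideal 1/fs grid
    pos = np.concatenate([[0], np.cumsum(gaps + 1)])
    n = int(pos[-1]) + 1
    t_full = t[0] + np.arange(n) / fs
    q_obs = records[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    q_full = np.empty((n, 4))
    for c in range(4):
        q_full[:, c] = np.interp(np.arange(n), pos, q_obs[:, c])
    q_full = normalize(q_full)
    filled = np.setdiff1d(np.arange(n), pos)
    series = QuaternionSeries(t_full, q_full, unit_id, {"filled": filled})
    # sanity: ingest invariants
    assert np.allclose(np.diff(t_full), 1.0 / fs, atol=1e-9)
    assert np.all(np.abs(series.norms() - 1.0) < INGEST_NORM_TOL)
    return series


def assemble_recording(
    raw: RawLog,
    fs: float = DEFAULT_FS,
    max_gap: int = DEFAULT_MAX_GAP,
    wrap: int = COUNTER_WRAP,
    label: str | None = None,
) -> Recording:
    """Fill gaps per unit and align the three units on a common time grid."""
    missing = sorted(set(UNIT_IDS) - set(raw.units))
    if missing:
        raise FormatError(f"log is missing unit(s): {missing}")
    filled = {
        u: fill_missing(raw.units[u], u, fs=fs, max_gap=max_gap, wrap=wrap) for u in UNIT_IDS
    }
    t0 = max(s.t[0] for s in filled.values())
    t1 = min(s.t[-1] for s in filled.values())
    if t1 <= t0:
        raise AlignmentError("units share no overlapping time range")
    aligned = {}
    for u, s in filled.items():
        i0 = int(round((t0 - s.t[0]) * fs))
        i1 = int(round((t1 - s.t[0]) * fs)) + 1
        aligned[u] = QuaternionSeries(s.t[i0:i1], s.q[i0:i1], u, dict(s.meta))
    meta = {"filled_counts": {u: int(len(filled[u].meta["filled"])) for u in UNIT_IDS}}
    return Recording(
        thorax=aligned["thorax"],
        abdomen=aligned["abdomen"],
        reference=aligned["reference"],
        fs=fs,
        label=label,
        subject_id=raw.subject_id,
        meta=meta,
    )


def load_recording(
    path,
    fs: float = DEFAULT_FS,
    max_gap: int = DEFAULT_MAX_GAP,
    label: str | None = None,
) -> Recording:
    """Convenience: :func:`parse_log` followed by :func:`assemble_recording`."""
    return assemble_recording(parse_log(path), fs=fs, max_gap=max_gap, label=label)


def trim_window(rec: Recording, start: float, end: float) -> Recording:
    """Cut all three series to the window ``[start, end)`` seconds.

    ``start``/``end`` are relative to the beginning of the recording.  Used to
    drop the initial transient while the orientation filter stabilizes and
    the subject settles into the activity.
    """
    if start < 0 or start >= end:
        raise BoundsError(f"invalid window [{start}, {end})")
    if end > rec.duration + 0.5 / rec.fs:
        raise BoundsError(
            f"window end {end:.2f}s exceeds recording duration {rec.duration:.2f}s"
        )
    i0 = int(round(start * rec.fs))
    i1 = int(round(end * rec.fs))
    i1 = min(i1, len(rec))

    def cut(s: QuaternionSeries) -> QuaternionSeries:
        return QuaternionSeries(s.t[i0:i1], s.q[i0:i1], s.unit_id, dict(s.meta))

    meta = dict(rec.meta)
    meta["trim"] = (float(start), float(end))
    return Recording(
        thorax=cut(rec.thorax),
        abdomen=cut(rec.abdomen),
        reference=cut(rec.reference),
        fs=rec.fs,
        label=rec.label,
        subject_id=rec.subject_id,
        meta=meta,
    )


def write_log(rec: Recording, path, drop: dict | None = None, wrap: int = COUNTER_WRAP) -> None:
    """Write a recording in the log dialect.

    ``drop`` maps unit ids to sample indices omitted from the file (used by
    the simulator to emulate lost transmissions); the per-unit counter keeps
    counting through dropped samples, so readers can recover the gaps.
    """
    drop = drop or {}
    frames = []
    for u in UNIT_IDS:
        s = rec.series(u)
        keep = np.ones(len(s), dtype=bool)
        idx = np.asarray(drop.get(u, []), dtype=int)
        if idx.size:
            keep[idx] = False
        counters = np.arange(len(s)) % wrap
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id or "anon",
                    "unit_id": u,
                    "counter": counters[keep],
                    "t": s.t[keep],
                    "qw": s.q[keep, 0],
                    "qx": s.q[keep, 1],
                    "qy": s.q[keep, 2],
                    "qz": s.q[keep, 3],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a ground-truth sidecar (``t,rr_true_bpm,activity``)."""
    truth.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t", "rr_true_bpm", "activity"]
    if list(df.columns) != expected:
        raise FormatError(f"unexpected sidecar header {list(df.columns)!r}")
    return df


def truth_path(log_path) -> str:
    """Sidecar path convention: ``rec.csv`` -> ``rec.truth.csv``."""
    p = str(log_path)
    return (p[:-4] if p.endswith(".csv") else p) + ".truth.csv"
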