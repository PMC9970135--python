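"""Human activity recognition from quaternion windows.

Recordings are segmented into non-overlapping 200-sample (20 s) windows whose
channels are the raw quaternion components of either the reference unit alone
(4 channels) or all three units (12 channels).  Channels are standardized
((x − μ)/σ fitted on the whole corpus, matching the published processing
order; a fit-on-train-only mode exists behind ``fit_on_train``), summarized
into per-channel time-domain and (optionally) frequency-domain features,
optionally class-balanced by downsampling to the smallest class, split
80/20 with a fixed seed, and fed to classical classifiers: KNN (k = 5,
Euclidean), random forest (Gini) and an RBF-kernel SVM with
``K(x1, x2) = exp(−‖x1 − x2‖² / (2σ²))``, σ = 1.

Task labels are merged before classification: the two sitting variants
become ``sitting`` and the two walking speeds become ``walking``, leaving
ten classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigError, EvaluationError
from .io import Recording

WINDOW_SAMPLES = 200  # 20 s at 10 Hz
TRAIN_FRACTION = 0.8
SPLIT_SEED = 42

LABEL_MERGES = {
    "sitting_support": "sitting",
    "sitting_no_support": "sitting",
    "walking_4kmh": "walking",
    "walking_6kmh": "walking",
}
HAR_CLASSES = (
    "cycling",
    "lying_left",
    "lying_right",
    "prone",
    "running",
    "sitting",
    "stairs",
    "standing",
    "supine",
    "walking",
)

TIME_FEATURES = ("mean", "std", "var", "kurtosis", "skewness", "ptp", "median", "iqr")
FREQ_FEATURES = ("fft_mean", "fft_std", "fft_skewness", "fft_max", "fft_min",
                 "psd_mean", "psd_max")

_COMPONENTS = ("qw", "qx", "qy", "qz")


def merge_label(label: str) -> str:
    """Apply the sitting/walking merges; other labels pass through."""
    return LABEL_MERGES.get(label, label)


@dataclass
class WindowedDataset:
    """Fixed-length labeled windows, shape ``(n_windows, length, channels)``."""

    X: np.ndarray
    y: np.ndarray  # merged activity labels
    subjects: np.ndarray
    channel_names: tuple

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 3:
            raise ValueError("X must be (n_windows, length, channels)")
        if self.X.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match the channel axis")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def window_length(self) -> int:
        return self.X.shape[1]


@dataclass
class StandardizationParams:
    """Per-channel mean and standard deviation fitted on a dataset."""

    mu: np.ndarray
    sigma: np.ndarray
    constant_channels: tuple = ()


@dataclass
class Split:
    """Train/test feature split produced by :func:`prepare_dataset`."""

    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class EvalMetrics:
    """Test-set metrics; precision/recall/F1 are macro-averaged."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    labels: tuple

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accuracy": self.accuracy,
                    "precision": self.precision,
                    "recall": self.recall,
                    "f1": self.f1,
                }
            ]
        )

    def confusion_text(self) -> str:
        df = pd.DataFrame(self.confusion, index=list(self.labels), columns=list(self.labels))
        return df.to_string()


def segment_windows(
    recordings: list[Recording],
    units: tuple = ("thorax", "abdomen", "reference"),
    length: int = WINDOW_SAMPLES,
) -> WindowedDataset:
    """Cut recordings into non-overlapping windows of ``length`` samples.

    The trailing remainder of each recording is dropped; recordings shorter
    than one window are skipped with a warning.  Labels are inherited from
    the recording with the sitting/walking merges applied.
    """
    windows, labels, subjects = [], [], []
    channel_names = tuple(f"{u}_{c}" for u in units for c in _COMPONENTS)
    for rec in recordings:
        if rec.label is None:
            raise ConfigError(f"recording {rec.subject_id!r} carries no activity label")
        data = np.concatenate([rec.series(u).q for u in units], axis=1)
        n_win = data.shape[0] // length
        if n_win == 0:
            warnings.warn(
                f"recording {rec.subject_id!r}/{rec.label!r} shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        label = merge_label(rec.label)
        for k in range(n_win):
            windows.append(data[k * length : (k + 1) * length])
            labels.append(label)
            subjects.append(rec.subject_id)
    X = np.stack(windows) if windows else np.zeros((0, length, len(channel_names)))
    return WindowedDataset(X, np.array(labels), np.array(subjects), channel_names)


def standardize(
    ds: WindowedDataset,
    params: StandardizationParams | None = None,
) -> tuple[WindowedDataset, StandardizationParams]:
    """Per-channel standardization ``(x − μ)/σ`` across all windows and samples.

    With ``params`` given, those statistics are applied (used to project new
    windows into an already-fitted feature space).  A constant channel
    (σ = 0) is emitted as all zeros and reported in
    ``params.constant_channels``.
    """
    flat = ds.X.reshape(-1, ds.X.shape[2])
    if params is None:
        mu = flat.mean(axis=0)
        sigma = flat.std(axis=0)
        constant = tuple(
            name for name, s in zip(ds.channel_names, sigma) if s == 0.0
        )
        if constant:
            warnings.warn(f"constant channel(s) standardized to zero: {constant}", stacklevel=2)
        params = StandardizationParams(mu=mu, sigma=sigma, constant_channels=constant)
    safe_sigma = np.where(params.sigma == 0.0, 1.0, params.sigma)
    Xs = (ds.X - params.mu) / safe_sigma
    return WindowedDataset(Xs, ds.y.copy(), ds.subjects.copy(), ds.channel_names), params


def _nan0(a: np.ndarray) -> np.ndarray:
    return np.nan_to_num(a, nan=0.0, posinf=0.0, neginf=0.0)


def extract_features(
    ds: WindowedDataset,
    include_frequency: bool = False,
    fs: float = 10.0,
) -> pd.DataFrame:
    """Per-channel feature table, one row per window.

    Time features (always): mean, standard deviation, variance, kurtosis
    (Fisher), skewness, peak-to-peak distance, median, interquartile range
    (linear-interpolation quartiles).  Frequency features (optional): mean,
    standard deviation, skewness, maximum and minimum of the FFT magnitude
    (zero-frequency bin excluded), and mean and maximum of the periodogram
    PSD (zero-frequency bin excluded).  Degenerate (constant) windows get
    zero kurtosis/skewness rather than NaN.  Columns are channel-major in
    the documented feature order, plus ``label`` and ``subject``.
    """
    X = ds.X  # (n, L, C)
    feats = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feats["mean"] = X.mean(axis=1)
        feats["std"] = X.std(axis=1)
        feats["var"] = X.var(axis=1)
        feats["kurtosis"] = _nan0(spstats.kurtosis(X, axis=1))
        feats["skewness"] = _nan0(spstats.skew(X, axis=1))
        feats["ptp"] = X.max(axis=1) - X.min(axis=1)
        feats["median"] = np.median(X, axis=1)
        q75, q25 = np.percentile(X, [75, 25], axis=1)
        feats["iqr"] = q75 - q25
        order = list(TIME_FEATURES)
        if include_frequency:
            mag = np.abs(np.fft.rfft(X, axis=1))[:, 1:, :]  # DC excluded
            feats["fft_mean"] = mag.mean(axis=1)
            feats["fft_std"] = mag.std(axis=1)
            feats["fft_skewness"] = _nan0(spstats.skew(mag, axis=1))
            feats["fft_max"] = mag.max(axis=1)
            feats["fft_min"] = mag.min(axis=1)
            _, psd = sps.periodogram(X, fs=fs, axis=1)
            psd = psd[:, 1:, :]
            feats["psd_mean"] = psd.mean(axis=1)
            feats["psd_max"] = psd.max(axis=1)
            order += list(FREQ_FEATURES)
    columns = {}
    for ci, ch in enumerate(ds.channel_names):
        for feat in order:
            columns[f"{ch}_{feat}"] = feats[feat][:, ci]
    table = pd.DataFrame(columns)
    table["label"] = ds.y
    table["subject"] = ds.subjects
    return table


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature columns of a feature table (label/subject dropped)."""
    return table.drop(columns=[c for c in ("label", "subject") if c in table.columns])


def prepare_dataset(
    table: pd.DataFrame,
    balance: bool = False,
    train_fraction: float = TRAIN_FRACTION,
    seed: int = SPLIT_SEED,
) -> Split:
    """Optional class balancing plus a seeded random 80/20 split.

    Balancing downsamples every class (uniform, without replacement) to the
    smallest class count.  The split is a plain seeded shuffle of the
    retained windows — not stratified — reproducible given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError("train_fraction must lie in (0, 1)")
    y = table["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ConfigError(f"class(es) with fewer than 2 windows: {sorted(small.index)}")
    rng = np.random.default_rng(seed)
    if balance:
        n_min = int(counts.min())
        kept = []
        for cls in sorted(counts.index):
            idx = np.flatnonzero(y == cls)
            kept.append(rng.choice(idx, size=n_min, replace=False))
        indices = np.sort(np.concatenate(kept))
    else:
        indices = np.arange(len(table))
    perm = rng.permutation(indices)
    n_train = int(round(train_fraction * perm.size))
    train_idx = perm[:n_train]
    test_idx = perm[n_train:]
    X = feature_matrix(table)
    return Split(
        X_train=X.iloc[train_idx].reset_index(drop=True),
        y_train=y[train_idx],
        X_test=X.iloc[test_idx].reset_index(drop=True),
        y_test=y[test_idx],
        train_idx=train_idx,
        test_idx=test_idx,
    )


def rbf_kernel_value(x1: np.ndarray, x2: np.ndarray, sigma: float = 1.0) -> float:
    """RBF kernel ``exp(−‖x1 − x2‖² / (2σ²))``."""
    d2 = float(np.sum((np.asarray(x1, float) - np.asarray(x2, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def build_model(model: str, k: int = 5, n_trees: int = 100, svm_sigma: float = 1.0,
                seed: int = SPLIT_SEED):
    """Classifier for one model name.

    Features are used at the scale they inherit from the standardized
    windows — there is no second, feature-level scaling step, matching the
    published processing order (standardize, segment, featurize, train).
    """
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    if model == "rf":
        return RandomForestClassifier(criterion="gini", n_estimators=n_trees, random_state=seed)
    if model == "svm":
        # K = exp(−d²/(2σ²))  ->  sklearn gamma = 1/(2σ²)
        return SVC(kernel="rbf", gamma=1.0 / (2.0 * svm_sigma**2))
    raise ConfigError(f"unknown model {model!r}; valid: knn, rf, svm")


def train_and_evaluate(
    split: Split,
    model: str = "knn",
    k: int = 5,
    n_trees: int = 100,
    svm_sigma: float = 1.0,
    seed: int = SPLIT_SEED,
) -> EvalMetrics:
    """Fit one classifier on the train split and score it on the test split."""
    unseen = sorted(set(split.y_test) - set(split.y_train))
    if unseen:
        raise EvaluationError(f"test class(es) absent from training: {unseen}")
    pipe = build_model(model, k=k, n_trees=n_trees, svm_sigma=svm_sigma, seed=seed)
    pipe.fit(split.X_train, split.y_train)
    pred = pipe.predict(split.X_test)
    labels = tuple(sorted(set(split.y_train) | set(split.y_test)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            split.y_test, pred, labels=labels, average="macro", zero_division=0
        )
    return EvalMetrics(
        accuracy=float(accuracy_score(split.y_test, pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        confusion=confusion_matrix(split.y_test, pred, labels=labels),
        labels=labels,
    )


def har_pipeline(
    recordings: list[Recording],
    units: str = "all",
    include_frequency: bool | None = None,
    balance: bool | None = None,
    models: tuple = ("knn", "rf", "svm"),
    seed: int = SPLIT_SEED,
    train_fraction: float = TRAIN_FRACTION,
    fit_on_train: bool = False,
) -> dict:
    """Windowing → standardization → features → split → all three models.

    ``units`` is ``"reference"`` (single-unit configuration: frequency
    features on, class imbalance kept) or ``"all"`` (three units: time
    features only, classes balanced) — each default can be overridden.
    With ``fit_on_train`` the channel standardization is fitted on the
    training windows only, avoiding the train/test leakage of the default
    fit-on-everything order.
    """
    unit_tuple = ("reference",) if units == "reference" else ("thorax", "abdomen", "reference")
    if units not in ("reference", "all"):
        raise ConfigError("units must be 'reference' or 'all'")
    if include_frequency is None:
        include_frequency = units == "reference"
    if balance is None:
        balance = units == "all"
    ds = segment_windows(recordings, units=unit_tuple)
    if fit_on_train:
        # features from raw windows; scaling happens inside the model pipeline
        raw_table = extract_features(ds, include_frequency=include_frequency)
        split = prepare_dataset(raw_table, balance=balance,
                                train_fraction=train_fraction, seed=seed)
    else:
        ds_std, _ = standardize(ds)
        table = extract_features(ds_std, include_frequency=include_frequency)
        split = prepare_dataset(table, balance=balance,
                                train_fraction=train_fraction, seed=seed)
    return {m: train_and_evaluate(split, model=m, seed=seed) for m in models}
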