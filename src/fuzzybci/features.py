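"""Spectral feature extraction for windowed EEG.

The pipeline mirrors the standard short-time spectral recipe for
command-classification BCIs: the recording is cut into 2-s windows with
50% overlap (256 samples at 128 Hz), each channel is mean-centred within
the window, a Hamming taper suppresses spectral leakage, and the DFT
magnitude at the first 64 bins (0–31.5 Hz, 0.5 Hz spacing — the
delta-through-gamma EEG range) of every channel is taken as a feature,
giving 64 x 14 = 896 features per window.  Features are then ranked by
information gain of the class given the (quantile-discretised) feature
and the top k (default 100) are kept, followed by min–max scaling with
bounds learned on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .eeg import Recording, Window, canonical_class_order, one_hot
from .errors import (
    BinRangeError,
    FeatureCountError,
    RecordingTooShortError,
    RecordingValidationError,
    SingleClassError,
)

DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP = 0.5
DEFAULT_N_BINS = 64
DEFAULT_DISC_BINS = 10
DEFAULT_TOP_K = 100


@dataclass
class FeatureMatrix:
    """Rows = windows, columns = named spectral features.

    ``labels`` holds 0-based class indices into ``class_names`` (or is
    ``None`` for unlabelled data).
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray | None = None
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise RecordingValidationError(
                "feature values must be N x F with one name per column"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise RecordingValidationError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise RecordingValidationError("feature values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.values.shape[0],):
                raise RecordingValidationError("labels must have one entry per row")
        self.class_names = tuple(self.class_names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def one_hot_targets(self) -> np.ndarray:
        if self.labels is None:
            raise RecordingValidationError("feature matrix has no labels")
        return one_hot(self.labels, len(self.class_names))

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[idx],
            self.feature_names,
            None if self.labels is None else self.labels[idx],
            self.class_names,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        if self.labels is not None:
            df["label"] = [self.class_names[i] for i in self.labels]
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"feature file not found: {path}")
        df = pd.read_csv(path)
        labels = None
        class_names: tuple[str, ...] = ()
        if "label" in df.columns:
            names = canonical_class_order(df["label"].astype(str).unique())
            lut = {n: i for i, n in enumerate(names)}
            labels = df["label"].astype(str).map(lut).to_numpy(dtype=np.int64)
            class_names = names
            df = df.drop(columns=["label"])
        return cls(
            df.to_numpy(dtype=np.float64),
            tuple(df.columns),
            labels,
            class_names,
        )


@dataclass
class FeatureRanking:
    """Per-feature information-gain scores (bits) and the descending order."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.order = np.asarray(self.order, dtype=np.int64)
        if self.scores.shape != self.order.shape:
            raise RecordingValidationError("scores and order must align")
        if (self.scores < -1e-12).any():
            raise RecordingValidationError("information gain cannot be negative")
        if sorted(self.order.tolist()) != list(range(self.order.size)):
            raise RecordingValidationError("order must be a permutation")


# ---------------------------------------------------------------------------
# Windowing and per-window transforms


def segment_windows(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> list[Window]:
    """Cut a recording into fixed-length windows with fractional overlap.

    Hop H = round(W * (1 - overlap)); trailing samples that do not fill a
    whole window are dropped.  Each window inherits the recording label.
    """
    if not (0 <= overlap < 1):
        raise RecordingValidationError("overlap must lie in [0, 1)")
    w_float = window_s * rec.sample_rate
    if abs(w_float - round(w_float)) > 1e-9 or round(w_float) <= 0:
        raise RecordingValidationError(
            "window_s x sample_rate must be a positive integer"
        )
    w = int(round(w_float))
    n = rec.n_samples
    if n < w:
        raise RecordingTooShortError(
            f"recording shorter than window: {n} < {w} samples"
        )
    hop = max(1, int(round(w * (1.0 - overlap))))
    count = (n - w) // hop + 1
    return [
        Window(
            data=rec.data[i * hop : i * hop + w],
            source_id=rec.source_id,
            start_index=i * hop,
            channels=rec.channels,
            sample_rate=rec.sample_rate,
            label=rec.label,
        )
        for i in range(count)
    ]


def center_channels(win: Window) -> Window:
    """Subtract each channel's within-window mean (zero-centring)."""
    data = win.data - win.data.mean(axis=0, keepdims=True)
    return Window(data, win.source_id, win.start_index, win.channels,
                  win.sample_rate, win.label)


def hamming_taper(length: int) -> np.ndarray:
    """Hamming coefficients h(t) = 0.54 - 0.46 cos(2 pi t / (W - 1))."""
    if length < 2:
        raise RecordingValidationError("Hamming taper needs W >= 2")
    return np.hamming(length)


def apply_hamming(win: Window) -> Window:
    """Multiply every channel by the Hamming taper."""
    h = hamming_taper(win.n_samples)
    return Window(win.data * h[:, None], win.source_id, win.start_index,
                  win.channels, win.sample_rate, win.label)


def spectral_feature_names(
    channels: Sequence[str],
    n_bins: int,
    sample_rate: float,
    window_len: int,
) -> tuple[str, ...]:
    df = sample_rate / window_len
    return tuple(
        f"{ch}@{i * df:g}Hz" for ch in channels for i in range(n_bins)
    )


def spectral_features(win: Window, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """DFT magnitude at bins 0..n_bins-1 per channel, channels concatenated.

    Expects a centred, Hamming-tapered window.  With W = 256 at 128 Hz the
    bin spacing is 0.5 Hz, so 64 bins cover 0–31.5 Hz.
    """
    w = win.n_samples
    if n_bins > w // 2:
        raise BinRangeError(f"n_bins {n_bins} exceeds W/2 = {w // 2}")
    if n_bins < 1:
        raise BinRangeError("n_bins must be >= 1")
    mags = np.abs(np.fft.rfft(win.data, axis=0))[:n_bins]  # (n_bins, C)
    return mags.T.reshape(-1)


def extract_features(
    recordings: Iterable[Recording],
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    n_bins: int = DEFAULT_N_BINS,
    spectral: bool = True,
) -> FeatureMatrix:
    """Full windowing + centring + Hamming + spectral pipeline.

    With ``spectral=False`` the centred, tapered time-domain samples are
    flattened instead of transformed (the alternative representation in
    which classification is applied to the combined raw windows).
    """
    recordings = list(recordings)
    if not recordings:
        raise RecordingValidationError("no recordings supplied")
    channels = recordings[0].channels
    rate = recordings[0].sample_rate
    rows: list[np.ndarray] = []
    label_names: list[str | None] = []
    window_len = None
    for rec in recordings:
        if rec.channels != channels:
            raise RecordingValidationError("recordings have mismatched channels")
        for win in segment_windows(rec, window_s, overlap):
            win = apply_hamming(center_channels(win))
            window_len = win.n_samples
            if spectral:
                rows.append(spectral_features(win, n_bins))
            else:
                rows.append(win.data.T.reshape(-1))
            label_names.append(win.label)
    assert window_len is not None
    if spectral:
        names = spectral_feature_names(channels, n_bins, rate, window_len)
    else:
        names = tuple(
            f"{ch}#t{t}" for ch in channels for t in range(window_len)
        )
    labels = None
    class_names: tuple[str, ...] = ()
    if all(ln is not None for ln in label_names):
        class_names = canonical_class_order([ln for ln in label_names if ln])
        lut = {n: i for i, n in enumerate(class_names)}
        labels = np.array([lut[ln] for ln in label_names], dtype=np.int64)
    return FeatureMatrix(np.vstack(rows), names, labels, class_names)


# ---------------------------------------------------------------------------
# Information-gain ranking, selection and scaling


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _quantile_bins(col: np.ndarray, n_disc_bins: int) -> np.ndarray:
    """Equal-frequency discretisation using order-statistic edges.

    Edges are actual data values (``method='lower'``), so bin membership
    is invariant under any strictly increasing transform of the feature.
    """
    qs = np.linspace(0, 1, n_disc_bins + 1)[1:-1]
    edges = np.unique(np.quantile(col, qs, method="lower"))
    return np.searchsorted(edges, col, side="right")


def info_gain_rank(
    fm: FeatureMatrix, n_disc_bins: int = DEFAULT_DISC_BINS
) -> FeatureRanking:
    """Rank features by InfoGain(Class, Feature) = H(Class) - H(Class | Feature).

    Continuous features are discretised into ``n_disc_bins`` equal-frequency
    bins; scores are in bits.  Ties are broken by ascending feature index.
    """
    if fm.labels is None:
        raise SingleClassError("information gain requires labelled data")
    if fm.n_samples < 2:
        raise SingleClassError("need at least two samples to rank features")
    y = fm.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("information gain needs >= 2 classes present")
    n_classes = int(y.max()) + 1
    class_counts = np.bincount(y, minlength=n_classes)
    h_class = _entropy_bits(class_counts)
    n = fm.n_samples
    scores = np.empty(fm.n_features)
    for f in range(fm.n_features):
        bins = _quantile_bins(fm.values[:, f], n_disc_bins)
        n_bins = int(bins.max()) + 1
        joint = np.bincount(bins * n_classes + y, minlength=n_bins * n_classes)
        joint = joint.reshape(n_bins, n_classes)
        h_cond = sum(
            (row.sum() / n) * _entropy_bits(row) for row in joint if row.sum()
        )
        scores[f] = max(0.0, h_class - h_cond)
    # stable sort on -score -> descending score, ties by ascending index
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(scores, order)


def select_top_k(
    fm: FeatureMatrix, ranking: FeatureRanking, k: int = DEFAULT_TOP_K
) -> FeatureMatrix:
    """Keep the k best-ranked features, in ranked order."""
    if not (1 <= k <= fm.n_features):
        raise FeatureCountError(
            f"k must be in [1, {fm.n_features}], got {k}"
        )
    keep = ranking.order[:k]
    return FeatureMatrix(
        fm.values[:, keep],
        tuple(fm.feature_names[i] for i in keep),
        fm.labels,
        fm.class_names,
    )


def feature_bounds(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (min, max) used for min–max scaling."""
    return fm.values.min(axis=0), fm.values.max(axis=0)


def apply_bounds(
    fm: FeatureMatrix, mins: np.ndarray, maxs: np.ndarray
) -> FeatureMatrix:
    """Min–max scale to [0, 1] with given bounds; values clipped to [0, 1].

    Zero-range features map to constant 0.
    """
    mins = np.asarray(mins, dtype=np.float64)
    maxs = np.asarray(maxs, dtype=np.float64)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((fm.values - mins) / safe, 0.0, 1.0)
    scaled[:, span <= 0] = 0.0
    return FeatureMatrix(scaled, fm.feature_names, fm.labels, fm.class_names)


def scale_features(
    train_fm: FeatureMatrix, apply_fm: FeatureMatrix | None = None
) -> FeatureMatrix:
    """Min–max scale ``apply_fm`` (default: the training matrix itself) using
    bounds learned from ``train_fm`` only."""
    target = train_fm if apply_fm is None else apply_fm
    if target.feature_names != train_fm.feature_names:
        raise RecordingValidationError("feature columns do not match")
    mins, maxs = feature_bounds(train_fm)
    return apply_bounds(target, mins, maxs)
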