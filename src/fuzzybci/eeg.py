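"""Domain types for multichannel EEG recordings and fixed-length windows.

A :class:`Recording` is a samples-by-channels matrix with a sampling rate
(128 Hz for the 14-channel consumer headset this package targets) and an
optional class label.  Recordings are exchanged as plain CSV with a header
row naming the channels; an optional leading ``time`` column is ignored on
read.  All downstream modules consume :class:`Recording` and
:class:`Window` objects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    NonFiniteValueError,
    NonNumericCellError,
    RaggedRowError,
    RecordingValidationError,
)

#: Electrode names of the 14-channel Emotiv-style montage, in channel order.
EMOTIV_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Recognised command-class names.  ``neutral`` is the resting pose; the
#: remaining six are the wheelchair commands the classifier can issue.
CLASS_NAMES: tuple[str, ...] = (
    "forward", "backward", "left", "right",
    "switch_on", "switch_off", "neutral",
)

DEFAULT_SAMPLE_RATE = 128.0


class ClassLabel(NamedTuple):
    """A named command class with its 0-based output index."""

    name: str
    index: int


def canonical_class_order(names: Sequence[str]) -> tuple[str, ...]:
    """Order a set of class names canonically (known names first, in
    :data:`CLASS_NAMES` order; unknown names appended alphabetically)."""
    present = set(names)
    ordered = [n for n in CLASS_NAMES if n in present]
    ordered += sorted(present - set(CLASS_NAMES))
    return tuple(ordered)


@dataclass
class Recording:
    """A multichannel EEG time series.

    Parameters
    ----------
    channels
        Ordered channel names (length C >= 1).
    data
        Samples-by-channels matrix in amplifier units (treated as
        unitless amplitudes).
    sample_rate
        Samples per second, > 0.  Default 128.
    label
        Optional class name for the whole recording.
    source_id
        Identifier used for window provenance (defaults to ``"recording"``).
    """

    channels: tuple[str, ...]
    data: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    label: str | None = None
    source_id: str = "recording"

    def __post_init__(self) -> None:
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) < 1:
            raise RecordingValidationError("a recording needs at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise RecordingValidationError("channel names must be unique")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise RecordingValidationError(
                f"data must be 2-D with {len(self.channels)} columns, "
                f"got shape {self.data.shape}"
            )
        if not self.sample_rate > 0:
            raise RecordingValidationError("sample_rate must be positive")
        if not np.isfinite(self.data).all():
            raise NonFiniteValueError("recording contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sample_rate


@dataclass
class Window:
    """One fixed-length segment of a recording (W samples x C channels)."""

    data: np.ndarray
    source_id: str
    start_index: int
    channels: tuple[str, ...] = field(default=EMOTIV_CHANNELS)
    sample_rate: float = DEFAULT_SAMPLE_RATE
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise RecordingValidationError(
                f"window data must be 2-D with {len(self.channels)} columns"
            )
        if self.start_index < 0:
            raise RecordingValidationError("start_index must be >= 0")
        if not np.isfinite(self.data).all():
            raise NonFiniteValueError("window contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


_NONFINITE_TOKENS = {"nan", "inf", "-inf", "+inf", "infinity", "-infinity"}


def read_recording(
    path: str | Path,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    label: str | None = None,
) -> Recording:
    """Read a CSV recording (header row = channel names, one row per sample).

    A leading column named ``time`` (case-insensitive) is dropped.  Raises
    :class:`FileNotFoundError` for a missing file, :class:`RaggedRowError`
    for rows with missing/extra fields, :class:`NonNumericCellError` for
    unparseable cells (naming the row and column) and
    :class:`NonFiniteValueError` for NaN/Inf samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    try:
        # keep_default_na=False: a literal "nan" cell must stay a string so
        # it is reported as a non-finite value, not as a missing field
        df = pd.read_csv(path, dtype=str, engine="python",
                         skipinitialspace=True, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise RaggedRowError(f"{path}: {exc}") from exc
    if df.shape[1] >= 1 and str(df.columns[0]).strip().lower() == "time":
        df = df.iloc[:, 1:]
    if df.shape[1] < 1:
        raise RecordingValidationError(f"{path}: no channel columns")

    values = np.empty(df.shape, dtype=np.float64)
    for col_idx, col in enumerate(df.columns):
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        missing = raw.isna() | (raw.str.strip() == "")
        if missing.any():
            row = int(np.flatnonzero(missing.to_numpy())[0])
            raise RaggedRowError(
                f"{path}: missing value at data row {row}, column '{col}'"
            )
        bad = numeric.isna().to_numpy()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            cell = str(raw.iloc[row]).strip().lower()
            if cell in _NONFINITE_TOKENS:
                raise NonFiniteValueError(
                    f"{path}: non-finite value at data row {row}, column '{col}'"
                )
            raise NonNumericCellError(
                f"{path}: non-numeric cell {raw.iloc[row]!r} at data row {row}, "
                f"column '{col}'"
            )
        values[:, col_idx] = numeric.to_numpy(dtype=np.float64)
    if not np.isfinite(values).all():
        raise NonFiniteValueError(f"{path}: recording contains non-finite samples")
    return Recording(
        channels=tuple(df.columns),
        data=values,
        sample_rate=sample_rate,
        label=label,
        source_id=path.stem,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV with a header row; full round-trip precision."""
    path = Path(path)
    df = pd.DataFrame(rec.data, columns=list(rec.channels))
    # Python float repr round-trips exactly, so read(write(x)) == x.
    df.to_csv(path, index=False)
    return path


def duration_seconds(n_samples: int, sample_rate: float) -> float:
    return n_samples / sample_rate


def make_class_labels(names: Sequence[str]) -> list[ClassLabel]:
    return [ClassLabel(name, i) for i, name in enumerate(names)]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Encode integer class indices as one-hot rows (desired network outputs)."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise RecordingValidationError("label index out of range")
    out = np.zeros((labels.shape[0], n_classes), dtype=np.float64)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _is_integer(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol


def samples_for(seconds: float, sample_rate: float) -> int:
    """Number of samples in a duration; must be integral."""
    n = seconds * sample_rate
    if not _is_integer(n) or n <= 0:
        raise RecordingValidationError(
            f"duration {seconds}s at {sample_rate} Hz is not a positive "
            "integer number of samples"
        )
    return int(round(n))
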