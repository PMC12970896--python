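"""Reading, calibrating and windowing single-channel EEG recordings.

Two plain dataset dialects are supported: one-ASCII-sample-per-line text
files (the convention of the classic Bonn epilepsy corpus, 4097 samples at
173.61 Hz per record) and MAT v5 files holding a single numeric vector (the
New Delhi sleep-centre convention, 1024 samples at 200 Hz).  Raw file values
are treated as ADC units and multiplied by a per-dataset ``calibration``
factor (µV per unit) before any amplitude-thresholded feature sees them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "Recording",
    "Window",
    "read_bonn_text",
    "write_bonn_text",
    "read_mat_segment",
    "segment",
    "bandpass_filter",
    "windows_to_manifest",
]

#: Default Bonn-corpus sampling rate in Hz.
BONN_FS = 173.61
#: Default New-Delhi-corpus sampling rate in Hz.
NDSC_FS = 200.0


@dataclass
class Recording:
    """A labeled single-channel EEG time series.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in µV (after calibration).
    fs : float
        Sampling frequency in Hz, > 0.
    recording_id : str
        Unique identifier, typically derived from the file name.
    label : str or None
        Categorical state, e.g. ``"ictal"`` / ``"interictal"`` /
        ``"preictal"`` or ``"seizure"`` / ``"non-seizure"``.
    calibration : float
        Multiplicative µV-per-unit factor that was applied to the raw file
        values (kept for provenance; ``samples`` are already calibrated).
    """

    samples: np.ndarray
    fs: float
    recording_id: str
    label: str | None = None
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not self.calibration > 0:
            raise ValueError(f"calibration must be > 0, got {self.calibration}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Window:
    """One fixed-length segment of a recording.

    ``start_sample = window_index * hop`` by construction; windows from one
    recording are strictly ordered by ``window_index``.  The window carries
    its parent ``recording_id`` so that downstream fold assignment and
    feature differencing never cross recording boundaries.
    """

    samples: np.ndarray
    recording_id: str
    window_index: int
    start_sample: int
    label: str | None = None
    fs: float = BONN_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


def read_bonn_text(
    path: str | Path,
    fs: float = BONN_FS,
    calibration: float = 1.0,
    label: str | None = None,
) -> Recording:
    """Read a one-sample-per-line ASCII EEG file.

    Each line must hold exactly one numeric token; values are multiplied by
    ``calibration`` (µV per raw unit).  The recording id is the file stem.

    Raises
    ------
    ValueError
        If the file is empty or a line does not parse as a number (the
        error names the offending 1-based line number).
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                values.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path.name}: non-numeric value {tok!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path.name}: empty file")
    samples = np.asarray(values, dtype=float) * calibration
    return Recording(samples, fs=fs, recording_id=path.stem, label=label,
                     calibration=calibration)


def write_bonn_text(recording: Recording, path: str | Path) -> None:
    """Write a recording in the one-sample-per-line text dialect.

    Integer-valued samples are written without a decimal point so that a
    read → write → read round trip is lossless for integer inputs.
    """
    with open(path, "w") as fh:
        for v in recording.samples:
            v = float(v)
            fh.write(f"{int(v)}\n" if v.is_integer() else f"{v!r}\n")


def read_mat_segment(
    path: str | Path,
    variable: str | None = None,
    fs: float = NDSC_FS,
    calibration: float = 1.0,
    label: str | None = None,
    expected_duration_s: float | None = None,
) -> Recording:
    """Read a single numeric vector from a MAT v5 file.

    If ``variable`` is None the file must contain exactly one numeric array;
    with several candidates an error listing them is raised.  The array is
    flattened to 1-D.  When ``expected_duration_s`` is given the sample
    count is checked against ``fs * expected_duration_s``.
    """
    path = Path(path)
    mat = scipy.io.loadmat(path)
    numeric = {
        k: v for k, v in mat.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
        and np.issubdtype(v.dtype, np.number) and v.size > 0
    }
    if not numeric:
        raise ValueError(f"{path.name}: no numeric vector found")
    if variable is None:
        if len(numeric) > 1:
            raise ValueError(
                f"{path.name}: multiple numeric variables {sorted(numeric)}; "
                "specify `variable`"
            )
        variable = next(iter(numeric))
    elif variable not in numeric:
        raise ValueError(
            f"{path.name}: variable {variable!r} not found; "
            f"candidates {sorted(numeric)}"
        )
    samples = np.asarray(numeric[variable], dtype=float).ravel() * calibration
    if expected_duration_s is not None:
        expected_n = round(fs * expected_duration_s)
        if len(samples) != expected_n:
            warnings.warn(
                f"{path.name}: {len(samples)} samples, expected {expected_n} "
                f"({expected_duration_s} s at {fs} Hz)"
            )
    return Recording(samples, fs=fs, recording_id=path.stem, label=label,
                     calibration=calibration)


def bandpass_filter(
    recording: Recording,
    lo: float = 0.5,
    hi: float = 70.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass (optional preprocessing hook).

    4th-order by default, applied forward and backward (``sosfiltfilt``) so
    the filter adds no phase distortion.  Off by default in every pipeline;
    mirrors the 0.5–70 Hz acquisition filtering of clinical scalp EEG.
    """
    nyq = recording.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for fs={recording.fs}")
    sos = butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    filtered = sosfiltfilt(sos, recording.samples)
    return Recording(np.asarray(filtered), fs=recording.fs,
                     recording_id=recording.recording_id,
                     label=recording.label, calibration=recording.calibration)


def segment(
    recording: Recording,
    window_len: int = 256,
    overlap_frac: float = 0.5,
) -> list[Window]:
    """Slice a recording into overlapping fixed-length windows.

    Windows start at offsets ``0, hop, 2*hop, ...`` with
    ``hop = round(window_len * (1 - overlap_frac))``; a trailing partial
    window is discarded.  For ``n >= window_len`` the count is
    ``floor((n - window_len)/hop) + 1``, otherwise the list is empty.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    hop = round(window_len * (1.0 - overlap_frac))
    if hop < 1:
        raise ValueError("hop computed as < 1; decrease overlap_frac")
    n = len(recording.samples)
    if n < window_len:
        return []
    count = (n - window_len) // hop + 1
    return [
        Window(
            samples=recording.samples[i * hop: i * hop + window_len],
            recording_id=recording.recording_id,
            window_index=i,
            start_sample=i * hop,
            label=recording.label,
            fs=recording.fs,
        )
        for i in range(count)
    ]


def windows_to_manifest(windows: Iterable[Window]) -> pd.DataFrame:
    """Serialize windows to a CSV-ready manifest table."""
    rows = [
        {
            "recording_id": w.recording_id,
            "window_index": w.window_index,
            "start_sample": w.start_sample,
            "label": w.label,
        }
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["recording_id", "window_index",
                                       "start_sample", "label"])
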