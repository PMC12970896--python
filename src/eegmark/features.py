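"""Window-level feature extraction: from recordings to the 5-feature table.

``extract_features`` slides the 256-sample / 50 %-overlap window over each
recording and computes the four base features per window: spike-wave
energy, sharp-wave energy (duration–amplitude transient detection),
Higuchi fractal dimension and permutation entropy.  The fifth feature, the
dynamic feature increment, depends on normalization bounds and is added
fold-locally by the evaluation module (or explicitly via
:func:`eegmark.dynamic.dfi`).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd

from .dynamic import BASE_FEATURES
from .nonlinear import HFDConfig, PEConfig, higuchi_fd, permutation_entropy
from .pathological import WaveCriteria, wave_energy
from .signal_io import Recording, Window, segment

__all__ = ["extract_window_features", "extract_features", "FEATURE_COLUMNS"]

#: All five feature columns in canonical order.
FEATURE_COLUMNS = BASE_FEATURES + ["dfi"]


def extract_window_features(
    window: Window,
    criteria: Sequence[WaveCriteria] | None = None,
    pe_cfg: PEConfig = PEConfig(),
    hfd_cfg: HFDConfig = HFDConfig(),
    detect_negative: bool = False,
) -> dict:
    """Base features of one window as a table row dict."""
    plf = wave_energy(window.samples, window.fs, criteria,
                      detect_negative=detect_negative)
    return {
        "recording_id": window.recording_id,
        "window_index": window.window_index,
        "label": window.label,
        "spike_energy": plf.spike_energy,
        "sharp_energy": plf.sharp_energy,
        "hfd": higuchi_fd(window.samples, hfd_cfg),
        "pe": permutation_entropy(window.samples, pe_cfg),
    }


def extract_features(
    recordings: Iterable[Recording],
    window_len: int = 256,
    overlap_frac: float = 0.5,
    criteria: Sequence[WaveCriteria] | None = None,
    pe_cfg: PEConfig = PEConfig(),
    hfd_cfg: HFDConfig = HFDConfig(),
    detect_negative: bool = False,
    warn_uncalibrated: bool = True,
) -> pd.DataFrame:
    """Feature table with one row per window over a set of recordings.

    Emits a warning when every recording has calibration 1.0 and µV
    amplitude thresholds are in play: raw ADC units that are not µV will
    silently distort the wave-energy features.
    """
    recordings = list(recordings)
    if warn_uncalibrated and recordings and all(
        r.calibration == 1.0 for r in recordings
    ):
        warnings.warn(
            "all recordings have calibration=1.0; wave-energy features "
            "apply µV thresholds — set a µV-per-unit calibration if the "
            "raw values are ADC units",
            stacklevel=2,
        )
    rows = []
    for rec in recordings:
        for win in segment(rec, window_len, overlap_frac):
            rows.append(extract_window_features(
                win, criteria, pe_cfg, hfd_cfg, detect_negative))
    cols = ["recording_id", "window_index", "label"] + BASE_FEATURES
    return pd.DataFrame(rows, columns=cols)
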