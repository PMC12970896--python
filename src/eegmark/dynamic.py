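"""Dynamic Feature Increment (DFI): state-transition sensitivity feature.

The DFI of window ``t`` within one recording is the sum over the four base
features (SpikeE, SharpE, HFD, PE) of the absolute first difference of the
min–max-normalized feature sequence:

    DFI_t = sum_f | norm_f(t) - norm_f(t-1) |,    DFI_0 = 0.

Normalization bounds are fit on a designated scope (in cross-validation,
the training fold only) and applied with clipping to [0, 1] elsewhere, so
DFI is always in [0, 4].  Differencing never crosses a recording boundary.
An alternative reading — absolute value of the summed differences,
``|sum_f Δf|`` — is available via ``convention="abs_sum"``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["normalize_sequence", "fit_bounds", "dfi", "BASE_FEATURES"]

#: The four base features that feed the DFI, in canonical column order.
BASE_FEATURES = ["spike_energy", "sharp_energy", "hfd", "pe"]


def fit_bounds(values: Sequence[float]) -> tuple[float, float]:
    """Per-feature (min, max) normalization bounds from the fitting scope."""
    arr = np.asarray(values, dtype=float)
    return float(arr.min()), float(arr.max())


def normalize_sequence(
    values: Sequence[float], bounds: tuple[float, float]
) -> np.ndarray:
    """Min–max scale to [0, 1] with clipping; degenerate bounds map to 0."""
    lo, hi = bounds
    arr = np.asarray(values, dtype=float)
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def dfi(
    features: pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    convention: str = "sum_abs",
    feature_cols: Sequence[str] = tuple(BASE_FEATURES),
) -> pd.Series:
    """Per-window DFI for a feature table of one or more recordings.

    ``features`` needs columns ``recording_id``, ``window_index`` and the
    base feature columns; ``bounds`` maps each base feature to its (min,
    max) fit scope.  Rows are processed per recording in window order and
    the first window of each recording gets DFI 0.  The returned Series is
    aligned to the input index.
    """
    if convention not in ("sum_abs", "abs_sum"):
        raise ValueError(f"unknown DFI convention {convention!r}")
    out = pd.Series(0.0, index=features.index, name="dfi")
    for _, grp in features.groupby("recording_id", sort=False):
        grp = grp.sort_values("window_index")
        normed = np.column_stack([
            normalize_sequence(grp[col].to_numpy(), bounds[col])
            for col in feature_cols
        ])
        diffs = np.diff(normed, axis=0)            # (n_windows-1, n_features)
        if convention == "sum_abs":
            vals = np.abs(diffs).sum(axis=1)
        else:
            vals = np.abs(diffs.sum(axis=1))
        out.loc[grp.index[1:]] = vals
    return out
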