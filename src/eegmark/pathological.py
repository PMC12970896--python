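"""Spike / sharp-wave detection and pathological wave-energy features.

Epileptiform transients are detected from duration–amplitude criteria:
a *spike* is a transient of 20–70 ms with amplitude exceeding 50 µV, a
*sharp wave* lasts 70–200 ms with amplitude of roughly 100–200 µV.  For
each window every strict local maximum becomes a candidate peak; its
support runs trough-to-trough, its duration is the trough-to-trough width
and its amplitude the peak value minus the mean of the two trough values
(a prominence-like measure robust to baseline drift).  Candidates whose
duration and amplitude fall inside a class's criteria are accepted
(spike checked first; same-class supports kept disjoint greedily), and
the per-class wave energy is the sum of squared sample values over each
accepted event's support, summed over events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WaveCriteria",
    "WaveEvent",
    "PathologicalFeatures",
    "default_criteria",
    "detect_candidate_peaks",
    "classify_and_measure",
    "wave_energy",
]


@dataclass(frozen=True)
class WaveCriteria:
    """Duration–amplitude acceptance band for one waveform class.

    ``duration_ms`` is closed-open ``[lo, hi)`` for spikes and closed
    ``[lo, hi]`` for sharp waves so that the 70 ms boundary belongs to the
    sharp class (the printed clinical ranges overlap there).  Amplitude is
    ``lo``-inclusive with an optionally unbounded upper limit.
    """

    wave_class: str                      # "spike" or "sharp"
    duration_ms: tuple[float, float]     # [lo, hi) for spike, [lo, hi] for sharp
    amplitude_uv: tuple[float, float]    # [lo, hi]; hi may be math.inf
    duration_hi_inclusive: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.duration_ms
        if not 0 < lo < hi:
            raise ValueError(f"invalid duration interval {self.duration_ms}")
        if self.amplitude_uv[0] < 0:
            raise ValueError("amplitude lower bound must be >= 0")

    def accepts(self, duration_ms: float, amplitude_uv: float) -> bool:
        lo, hi = self.duration_ms
        if self.duration_hi_inclusive:
            dur_ok = lo <= duration_ms <= hi
        else:
            dur_ok = lo <= duration_ms < hi
        alo, ahi = self.amplitude_uv
        return dur_ok and alo <= amplitude_uv <= ahi


def default_criteria(sharp_amplitude_cap: float = 200.0) -> list[WaveCriteria]:
    """The clinical duration–amplitude bands, spike first.

    Spike: 20–70 ms (right-open), amplitude > 50 µV unbounded above.
    Sharp: 70–200 ms (closed), amplitude 100–``sharp_amplitude_cap`` µV;
    pass ``math.inf`` to lift the approximate 200 µV upper bound.
    """
    return [
        WaveCriteria("spike", (20.0, 70.0), (50.0, math.inf)),
        WaveCriteria("sharp", (70.0, 200.0), (100.0, sharp_amplitude_cap),
                     duration_hi_inclusive=True),
    ]


@dataclass
class WaveEvent:
    """One accepted pathological waveform."""

    wave_class: str
    peak_index: int
    left_trough: int
    right_trough: int
    duration_ms: float
    amplitude_uv: float
    energy_uv2: float

    @property
    def support(self) -> tuple[int, int]:
        """Closed sample-index interval [left_trough, right_trough]."""
        return (self.left_trough, self.right_trough)


@dataclass
class PathologicalFeatures:
    """Per-window wave-energy summary (SpikeE / SharpE plus counts)."""

    spike_energy: float = 0.0
    sharp_energy: float = 0.0
    spike_count: int = 0
    sharp_count: int = 0
    events: list[WaveEvent] = field(default_factory=list)


def _descend(x: np.ndarray, start: int, step: int) -> int:
    """Walk from ``start`` while samples strictly decrease; return stop index.

    Stops at the first non-decrease (a tie counts as the minimum) or at the
    array edge, which is treated as a trough.
    """
    i = start
    n = len(x)
    while 0 < i if step < 0 else i < n - 1:
        j = i + step
        if x[j] < x[i]:
            i = j
        else:
            break
    return i


def detect_candidate_peaks(samples: Sequence[float]) -> list[tuple[int, int, int]]:
    """Find all strict local maxima with their flanking troughs.

    Returns sorted, peak-disjoint triples ``(left_trough, peak_index,
    right_trough)``.  A peak is a sample strictly greater than both
    neighbours; troughs are found by strict descent on each side, with the
    window edges counting as troughs.  Constant or monotone inputs yield no
    peaks.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return []
    interior = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
    return [(_descend(x, p, -1), int(p), _descend(x, p, +1)) for p in interior]


def classify_and_measure(
    triple: tuple[int, int, int],
    samples: Sequence[float],
    fs: float,
    criteria: Sequence[WaveCriteria] | None = None,
) -> WaveEvent | None:
    """Measure one peak triple and classify it against the criteria.

    Duration is the trough-to-trough width in ms; amplitude is the peak
    value minus the mean of the two trough values.  The first criteria
    entry whose bands contain the measurements wins (spike before sharp in
    the defaults); returns None if no class accepts.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if criteria is None:
        criteria = default_criteria()
    x = np.asarray(samples, dtype=float)
    left, peak, right = triple
    if not 0 <= left < peak < right <= len(x) - 1:
        raise ValueError(f"invalid peak triple {triple} for window of {len(x)}")
    duration_ms = (right - left) / fs * 1000.0
    amplitude = x[peak] - 0.5 * (x[left] + x[right])
    for crit in criteria:
        if crit.accepts(duration_ms, amplitude):
            energy = float(np.sum(x[left:right + 1] ** 2))
            return WaveEvent(crit.wave_class, peak, left, right,
                             duration_ms, float(amplitude), energy)
    return None


def wave_energy(
    samples: Sequence[float],
    fs: float,
    criteria: Sequence[WaveCriteria] | None = None,
    detect_negative: bool = False,
) -> PathologicalFeatures:
    """Accumulate per-class pathological wave energy for one window.

    Candidates are scanned left to right; within each class an event whose
    closed support overlaps an already accepted same-class support is
    dropped, so same-class supports are pairwise disjoint.  With
    ``detect_negative`` the sign-flipped signal is scanned as well, picking
    up downward-going transients (off by default: only local maxima are
    considered).
    """
    if criteria is None:
        criteria = default_criteria()
    feats = PathologicalFeatures()
    signals = [np.asarray(samples, dtype=float)]
    if detect_negative:
        signals.append(-signals[0])
    for sig in signals:
        last_end: dict[str, int] = {}
        for triple in detect_candidate_peaks(sig):
            event = classify_and_measure(triple, sig, fs, criteria)
            if event is None:
                continue
            prev = last_end.get(event.wave_class)
            if prev is not None and event.left_trough <= prev:
                continue
            last_end[event.wave_class] = event.right_trough
            feats.events.append(event)
            if event.wave_class == "spike":
                feats.spike_energy += event.energy_uv2
                feats.spike_count += 1
            else:
                feats.sharp_energy += event.energy_uv2
                feats.sharp_count += 1
    return feats
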