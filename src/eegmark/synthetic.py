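"""Synthetic labeled EEG with ground-truth pathological events.

Each state (interictal / preictal / ictal) is described by a
:class:`StateProfile`: a colored-noise background (power ~ 1/f^exponent)
blended with a deterministic oscillation whose amplitude fraction is the
``regularity`` knob, plus Poisson-injected raised-cosine (Hann) transients
whose widths and amplitudes are drawn inside the clinical spike
(20–70 ms, >50 µV) and sharp-wave (70–200 ms, ~100–200 µV) bands.  The
Hann shape is smooth and single-peaked with analytically controlled
trough-to-trough width, so each injected event's true class, support and
added energy are computable in closed form and logged.

Default profiles realize the qualitative state structure the features are
designed to pick up: event rates rise (0.05 → 0.5 → 2 spikes/s) and
regularity rises (0.2 → 0.4 → 0.7) from interictal through preictal to
ictal, so ictal segments carry more pathological wave energy and lower
signal complexity (PE, HFD) than interictal ones, with preictal in
between.  Ictal event amplitudes are shifted up, and a per-recording
regularity jitter plus a shared nuisance oscillation-frequency band model
inter-subject variability so that the transient-energy features — not the
complexity features — are the most discriminative family, as in clinical
EEG.  These are fixture parameters, not claims about physiology.

Everything is driven by one master seed through ``numpy`` SeedSequence
spawning: identical seed, bit-identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pathological import WaveCriteria, default_criteria
from .signal_io import BONN_FS, Recording

__all__ = [
    "StateProfile",
    "InjectedEvent",
    "SynthDataset",
    "default_profiles",
    "generate_background",
    "inject_events",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class StateProfile:
    """Generator parameters for one brain state.

    Rates are events/s; width intervals are ms; amplitude intervals are µV
    (drawn uniformly); ``regularity`` in [0, 1] is the amplitude fraction
    of the deterministic oscillation in the background blend, jittered per
    recording by ±``regularity_jitter`` (truncated to [0, 1]) to model
    inter-subject variability; the oscillation frequency is drawn per
    recording from the ``oscillation_hz`` interval — a shared nuisance
    range keeps frequency from becoming a state cue on its own;
    ``noise_exponent`` shapes the noise spectrum (0 = white, 1 = pink);
    ``background_uv`` is the background RMS in µV.
    """

    state: str
    spike_rate: float = 0.0
    sharp_rate: float = 0.0
    spike_width_ms: tuple[float, float] = (25.0, 65.0)
    spike_amplitude_uv: tuple[float, float] = (60.0, 150.0)
    sharp_width_ms: tuple[float, float] = (80.0, 190.0)
    sharp_amplitude_uv: tuple[float, float] = (110.0, 190.0)
    noise_exponent: float = 1.0
    background_uv: float = 20.0
    oscillation_hz: tuple[float, float] = (8.0, 8.0)
    regularity: float = 0.2
    regularity_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.spike_rate < 0 or self.sharp_rate < 0:
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must be in [0, 1]")


def default_profiles() -> dict[str, StateProfile]:
    """The three default state profiles (see module docstring)."""
    shared = dict(regularity_jitter=0.35, background_uv=15.0,
                  oscillation_hz=(6.0, 11.0))
    return {
        "interictal": StateProfile(
            "interictal", spike_rate=0.05, sharp_rate=0.05,
            regularity=0.2, **shared),
        "preictal": StateProfile(
            "preictal", spike_rate=0.5, sharp_rate=0.75,
            regularity=0.4, **shared),
        "ictal": StateProfile(
            "ictal", spike_rate=2.0, sharp_rate=2.0,
            regularity=0.7,
            spike_amplitude_uv=(120.0, 200.0),
            sharp_amplitude_uv=(150.0, 195.0), **shared),
    }


@dataclass
class InjectedEvent:
    """Ground truth for one injected transient."""

    wave_class: str          # class under the clinical criteria ("spike"/"sharp")
    start: int               # first sample of the pulse (left trough)
    peak_index: int          # center sample (the pulse maximum)
    end: int                 # last sample of the pulse (right trough)
    duration_ms: float       # trough-to-trough width actually realized
    amplitude_uv: float      # peak height above the zero troughs
    energy_uv2: float        # sum of squared pulse samples (exact added energy)


@dataclass
class SynthDataset:
    """Generated recordings plus their per-recording ground-truth logs."""

    recordings: list[Recording]
    event_logs: dict[str, list[InjectedEvent]]
    profiles: dict[str, StateProfile]
    master_seed: int


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum ~ 1/f^exponent (spectral shaping)."""
    white = rng.standard_normal(n)
    if exponent == 0.0:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        scale = np.ones_like(freqs)
        nz = freqs > 0
        scale[nz] = freqs[nz] ** (-exponent / 2.0)
        scale[0] = 0.0
        out = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def generate_background(
    n: int,
    fs: float,
    profile: StateProfile,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Colored-noise background blended with the profile's oscillation.

    The noise and a random-phase sinusoid are each normalized to unit RMS
    and combined with amplitude weights ``(1 - regularity, regularity)``,
    then scaled to ``background_uv`` RMS-equivalent µV.  ``regularity`` 0
    is pure noise; 1 is a pure sinusoid (low-complexity floor).  The
    realized regularity is jittered by ±``regularity_jitter`` and the
    oscillation frequency drawn from the profile's interval, both from
    ``rng`` (one draw per call, i.e. per recording).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    if profile.background_uv == 0.0:
        return np.zeros(n)
    noise = _colored_noise(n, profile.noise_exponent, rng) if n > 1 \
        else rng.standard_normal(1)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * math.pi)
    f_lo, f_hi = profile.oscillation_hz
    freq = rng.uniform(f_lo, f_hi) if f_hi > f_lo else f_lo
    sine = math.sqrt(2.0) * np.sin(2 * math.pi * freq * t + phase)  # unit RMS
    r = profile.regularity
    if profile.regularity_jitter > 0:
        r = float(np.clip(
            r + rng.uniform(-profile.regularity_jitter,
                            profile.regularity_jitter), 0.0, 1.0))
    return profile.background_uv * ((1.0 - r) * noise + r * sine)


def _hann_pulse(width_samples: int, amplitude: float) -> np.ndarray:
    """Raised-cosine pulse over ``width_samples`` samples (odd, >= 5).

    Endpoints are exactly zero (the troughs), the center sample is exactly
    ``amplitude`` (the peak); values decrease strictly from center to ends.
    """
    i = np.arange(width_samples)
    return amplitude * 0.5 * (1.0 - np.cos(2 * math.pi * i /
                                           (width_samples - 1)))


def _draw_pulse(
    kind: str, fs: float, profile: StateProfile, rng: np.random.Generator,
    criteria: Sequence[WaveCriteria],
) -> tuple[np.ndarray, str, float, float]:
    """Draw one pulse; returns (samples, true class, duration_ms, amplitude)."""
    if kind == "spike":
        w_lo, w_hi = profile.spike_width_ms
        a_lo, a_hi = profile.spike_amplitude_uv
    else:
        w_lo, w_hi = profile.sharp_width_ms
        a_lo, a_hi = profile.sharp_amplitude_uv
    width_ms = rng.uniform(w_lo, w_hi)
    amplitude = rng.uniform(a_lo, a_hi)
    # odd sample count >= 5 whose trough-to-trough width approximates width_ms
    L = int(round(width_ms / 1000.0 * fs)) + 1
    if L % 2 == 0:
        L += 1
    L = max(L, 5)
    duration_ms = (L - 1) / fs * 1000.0
    true_class = "none"
    for crit in criteria:
        if crit.accepts(duration_ms, amplitude):
            true_class = crit.wave_class
            break
    return _hann_pulse(L, amplitude), true_class, duration_ms, amplitude


def inject_events(
    background: np.ndarray,
    fs: float,
    profile: StateProfile,
    rng: np.random.Generator | int | None = None,
    criteria: Sequence[WaveCriteria] | None = None,
    max_retries: int = 1000,
) -> tuple[np.ndarray, list[InjectedEvent]]:
    """Add Poisson-timed non-overlapping Hann transients to a background.

    Event counts are Poisson with mean ``rate * duration``; placements are
    uniform with a 2-sample guard gap between supports (rejection with
    bounded retries).  The log records each event's true class under the
    clinical criteria, its support, realized duration/amplitude and the
    exact added energy (sum of squared pulse samples).

    Raises
    ------
    RuntimeError
        If non-overlapping placement fails after ``max_retries`` attempts
        (rate too high for the recording length).
    """
    rng = np.random.default_rng(rng)
    if criteria is None:
        criteria = default_criteria()
    x = np.asarray(background, dtype=float).copy()
    n = x.size
    duration_s = n / fs
    occupied = np.zeros(n, dtype=bool)
    log: list[InjectedEvent] = []
    for kind, rate in (("spike", profile.spike_rate),
                       ("sharp", profile.sharp_rate)):
        count = rng.poisson(rate * duration_s)
        for _ in range(count):
            pulse, true_class, duration_ms, amplitude = _draw_pulse(
                kind, fs, profile, rng, criteria)
            L = pulse.size
            if L + 4 > n:
                raise RuntimeError("event width exceeds recording length")
            placed = False
            for _attempt in range(max_retries):
                start = int(rng.integers(0, n - L + 1))
                lo = max(0, start - 2)
                hi = min(n, start + L + 2)
                if not occupied[lo:hi].any():
                    occupied[start:start + L] = True
                    x[start:start + L] += pulse
                    log.append(InjectedEvent(
                        wave_class=true_class,
                        start=start,
                        peak_index=start + (L - 1) // 2,
                        end=start + L - 1,
                        duration_ms=duration_ms,
                        amplitude_uv=amplitude,
                        energy_uv2=float(np.sum(pulse**2)),
                    ))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place non-overlapping {kind} after "
                    f"{max_retries} retries (rate too high)")
    log.sort(key=lambda e: e.start)
    return x, log


def generate_recording(
    profile: StateProfile,
    duration_s: float = 23.6,
    fs: float = BONN_FS,
    seed: int | np.random.Generator | None = None,
    recording_id: str = "synthetic",
    criteria: Sequence[WaveCriteria] | None = None,
) -> tuple[Recording, list[InjectedEvent]]:
    """One synthetic labeled recording plus its ground-truth event log."""
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    background = generate_background(n, fs, profile, rng)
    samples, log = inject_events(background, fs, profile, rng, criteria)
    rec = Recording(samples, fs=fs, recording_id=recording_id,
                    label=profile.state)
    return rec, log


def generate_dataset(
    n_per_state: int,
    duration_s: float = 23.6,
    fs: float = BONN_FS,
    profiles: dict[str, StateProfile] | None = None,
    master_seed: int = 0,
    criteria: Sequence[WaveCriteria] | None = None,
) -> SynthDataset:
    """A labeled multi-recording dataset, deterministic given the seed.

    Generates ``n_per_state`` recordings per profile state; the feature
    direction structure (higher wave energy, lower PE/HFD in ictal than
    interictal, preictal intermediate) holds in expectation at the default
    profiles.
    """
    if profiles is None:
        profiles = default_profiles()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(profiles) * max(n_per_state, 0))
    recordings: list[Recording] = []
    logs: dict[str, list[InjectedEvent]] = {}
    i = 0
    for state in profiles:
        for j in range(n_per_state):
            rid = f"{state}_{j:03d}"
            rec, log = generate_recording(
                profiles[state], duration_s, fs,
                seed=np.random.default_rng(children[i]),
                recording_id=rid, criteria=criteria)
            recordings.append(rec)
            logs[rid] = log
            i += 1
    return SynthDataset(recordings=recordings, event_logs=logs,
                        profiles=dict(profiles), master_seed=master_seed)
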