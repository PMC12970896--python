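"""Nonlinear dynamical features: permutation entropy and Higuchi fractal dimension.

Permutation entropy (PE) is the Shannon entropy, in nats, of the
distribution of ordinal patterns among delay-embedded subsequences of the
signal: for embedding dimension ``m`` and delay ``tau`` each of the
``M = n - (m-1)*tau`` embedding vectors is reduced to the permutation that
sorts it ascending (ties broken by earlier index), and
``H = -sum_l P_l ln P_l`` over the pattern frequencies.  Regular signals
concentrate on few patterns (H near 0); white noise approaches the uniform
limit ``ln(m!)``.

The Higuchi fractal dimension (HFD) estimates a curve's fractal dimension
from average normalized curve lengths at scales ``k = 1..k_max``:

    L_m(k) = (1/k) * sum_i |x(m+ik) - x(m+(i-1)k)| * (N-1) / (floor((N-m)/k) * k)

with 1-based indexing and ``<L(k)>`` the mean over offsets ``m = 1..k``.
``ln<L(k)>`` scales as ``-HFD * ln k``; the negated slope of the unweighted
least-squares fit is the estimate.  Smooth curves give ~1, uncorrelated
noise ~2.

Defaults (m=3, tau=1, k_max=10) suit 256-sample EEG windows: 3! = 6
patterns against 254 usable vectors is adequate sampling, and k_max=10
keeps every scale's subsequences long enough.  Both estimators are
deterministic: identical input gives bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PEConfig",
    "HFDConfig",
    "ordinal_pattern_distribution",
    "permutation_entropy",
    "curve_length_at_scale",
    "higuchi_fd",
]


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy settings: embedding dimension and delay."""

    m: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")


@dataclass(frozen=True)
class HFDConfig:
    """Higuchi settings: maximum scale factor."""

    k_max: int = 10

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


def _embedding_patterns(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Ordinal pattern (stable argsort index tuple) of every embedding vector.

    Returns an (M, m) integer array; row j is the index order that sorts
    the j-th delay vector ascending, ties broken by earlier index.
    """
    n = x.size
    M = n - (m - 1) * tau
    if M < 1:
        raise ValueError(
            f"sequence of length {n} too short for m={m}, tau={tau} "
            f"(needs at least {(m - 1) * tau + 1} samples)"
        )
    idx = np.arange(M)[:, None] + np.arange(m)[None, :] * tau
    return np.argsort(x[idx], axis=1, kind="stable")


def ordinal_pattern_distribution(
    samples: Sequence[float], cfg: PEConfig = PEConfig()
) -> dict[tuple[int, ...], float]:
    """Relative frequency of each ordinal pattern among the delay vectors.

    Keys are permutations as index tuples (the stable ascending sort order
    of Eq-style ranking); values sum to 1 and at most ``min(m!, M)``
    patterns appear.
    """
    x = np.asarray(samples, dtype=float)
    patterns = _embedding_patterns(x, cfg.m, cfg.tau)
    uniq, counts = np.unique(patterns, axis=0, return_counts=True)
    total = counts.sum()
    return {tuple(int(i) for i in row): c / total
            for row, c in zip(uniq, counts)}


def permutation_entropy(
    samples: Sequence[float],
    cfg: PEConfig = PEConfig(),
    normalized: bool = False,
) -> float:
    """Permutation entropy in nats; optionally normalized by ln(m!).

    Lies in [0, ln(m!)]; 0 for any strictly monotone sequence (a single
    pattern).  ``0 * ln 0`` terms are dropped.
    """
    x = np.asarray(samples, dtype=float)
    patterns = _embedding_patterns(x, cfg.m, cfg.tau)
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log(p))) + 0.0  # normalize -0.0 to 0.0
    if normalized:
        h /= math.log(math.factorial(cfg.m))
    return h


def curve_length_at_scale(samples: Sequence[float], k: int, m_start: int) -> float:
    """Normalized Higuchi curve length ``L_m(k)`` for one offset.

    ``m_start`` is the 1-based offset in ``1..k``.  The subsequence is
    ``x(m), x(m+k), x(m+2k), ...``; its absolute increments are summed and
    normalized by ``(N-1)/(floor((N-m)/k)*k)`` then divided by ``k``.

    Raises
    ------
    ValueError
        If the subsequence has fewer than 2 points (no increment exists).
    """
    x = np.asarray(samples, dtype=float)
    N = x.size
    if not 1 <= m_start <= k:
        raise ValueError(f"m_start must be in 1..{k}, got {m_start}")
    n_inc = (N - m_start) // k
    if n_inc < 1:
        raise ValueError(f"subsequence for k={k}, m={m_start} has < 2 points")
    sub = x[m_start - 1:: k][: n_inc + 1]
    total = float(np.sum(np.abs(np.diff(sub))))
    return total * (N - 1) / (n_inc * k) / k


def higuchi_fd(samples: Sequence[float], cfg: HFDConfig = HFDConfig()) -> float:
    """Higuchi fractal dimension via the log–log curve-length slope.

    Averages ``L_m(k)`` over offsets ``m = 1..k`` for each ``k = 1..k_max``
    (offsets whose subsequence has < 2 points are excluded from the
    average) and returns the negated OLS slope of ``ln<L(k)>`` on ``ln k``.
    A constant signal has zero curve length at every scale; the estimate is
    defined as 0.0 and a warning is emitted rather than raising.
    """
    x = np.asarray(samples, dtype=float)
    N = x.size
    if N < 2 * cfg.k_max:
        raise ValueError(f"need n >= 2*k_max = {2 * cfg.k_max}, got {N}")
    log_k = []
    log_L = []
    for k in range(1, cfg.k_max + 1):
        lengths = []
        for m_start in range(1, k + 1):
            if (N - m_start) // k >= 1:
                lengths.append(curve_length_at_scale(x, k, m_start))
        mean_L = float(np.mean(lengths))
        if mean_L <= 0.0:
            warnings.warn(
                "zero curve length (constant signal); HFD defined as 0.0"
            )
            return 0.0
        log_k.append(math.log(k))
        log_L.append(math.log(mean_L))
    slope = np.polyfit(log_k, log_L, 1)[0]
    return float(-slope)
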