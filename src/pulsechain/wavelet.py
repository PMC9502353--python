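"""Maximal-overlap discrete wavelet transform (MODWT) band filtering.

The undecimated transform keeps every coefficient sequence at the input
length, which makes it shift-invariant and lets whole dyadic frequency
bands be kept or dropped before exact inverse reconstruction.  Detail
level ``j`` of a signal sampled at ``fs`` covers, nominally,
``[fs/2**(j+1), fs/2**j]`` Hz, and the level-``L`` approximation covers
``[0, fs/2**(L+1)]`` Hz.

Two presets implement the ECG and PPG band filters used by the chain:

* ECG (nominally 130 Hz): symlet-4, 10 levels, rejecting D1-D2
  (16.25-65 Hz high-frequency noise) and the approximation
  (< 0.064 Hz baseline wander).
* PPG (nominally 25 Hz): coiflet-1, 4 levels, keeping only D3-D4
  (0.78-3.12 Hz, i.e. pulse rates of roughly 47-187 bpm).

Boundary handling is circular (periodic), which keeps reconstruction
exact; the first/last ``(2**L - 1) * (taps - 1)`` samples are
boundary-affected and flagged at debug level.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .signal_model import UniformSignal

__all__ = [
    "WaveletDecomposition",
    "BandEdges",
    "modwt",
    "reconstruct",
    "band_edges",
    "filter_ecg",
    "filter_ppg",
    "truncate2",
]

logger = logging.getLogger(__name__)

#: wavelets exercised by the presets; any pywt discrete wavelet works
SUPPORTED_WAVELETS = ("sym4", "coif1", "db4", "haar")

# absolute pass band of the PPG preset (from the 25 Hz dyadic edges)
PPG_BAND_HZ = (25.0 / 32.0, 25.0 / 8.0)
# ECG preset: reject details at/above this edge and the slow approximation
ECG_REJECT_ABOVE_HZ = 16.25
ECG_APPROX_BELOW_HZ = 0.064


@dataclass(frozen=True)
class BandEdges:
    """Nominal frequency support of one decomposition component."""

    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"require 0 <= f_lo < f_hi, got {self.f_lo}, {self.f_hi}")


@dataclass(frozen=True)
class WaveletDecomposition:
    """MODWT coefficients: L detail sequences plus one approximation.

    All sequences have the input length (maximal-overlap property).
    """

    details: tuple
    approximation: np.ndarray
    wavelet_name: str
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "details", tuple(np.asarray(d, dtype=float) for d in self.details)
        )
        object.__setattr__(
            self, "approximation", np.asarray(self.approximation, dtype=float)
        )
        n = self.approximation.size
        if any(d.size != n for d in self.details):
            raise ValueError("all coefficient sequences must share the input length")

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def n(self) -> int:
        return self.approximation.size


def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        w = pywt.Wavelet(wavelet)
    except ValueError:
        raise ValueError(f"unknown wavelet name: {wavelet!r}") from None
    # MODWT rescaling of the orthonormal filter pair
    g = np.asarray(w.dec_lo, dtype=float) / math.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / math.sqrt(2.0)
    return g, h


def modwt(signal: UniformSignal, wavelet: str = "sym4", levels: int = 4) -> WaveletDecomposition:
    """Decompose with the maximal-overlap pyramid (circular boundary).

    ``levels`` must satisfy ``levels <= floor(log2(n))``.
    """
    n = signal.n
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > math.floor(math.log2(n)):
        raise ValueError(
            f"{levels} levels need at least {2 ** levels} samples, got {n}"
        )
    g, h = _filters(wavelet)
    v = signal.values.astype(float)
    details = []
    for j in range(1, levels + 1):
        stride = 2 ** (j - 1)
        w_j = np.zeros(n)
        v_j = np.zeros(n)
        for tap, (g_l, h_l) in enumerate(zip(g, h)):
            shifted = np.roll(v, stride * tap)
            w_j += h_l * shifted
            v_j += g_l * shifted
        details.append(w_j)
        v = v_j
    n_boundary = min(n, (2 ** levels - 1) * (len(g) - 1))
    logger.debug(
        "modwt(%s, L=%d): first/last %d samples are boundary-affected (circular)",
        wavelet, levels, n_boundary,
    )
    return WaveletDecomposition(tuple(details), v, wavelet, signal.fs, signal.t0)


def reconstruct(
    decomp: WaveletDecomposition,
    keep_details: set[int] | None = None,
    keep_approximation: bool = True,
) -> UniformSignal:
    """Inverse MODWT keeping only the requested components.

    ``keep_details`` uses 1-based level indices; ``None`` keeps all levels.
    Reconstruction is linear in the kept components and exact when
    everything is kept.
    """
    levels = decomp.levels
    if keep_details is None:
        keep_details = set(range(1, levels + 1))
    keep_details = set(keep_details)
    bad = keep_details - set(range(1, levels + 1))
    if bad:
        raise ValueError(f"invalid detail level indices {sorted(bad)}; have 1..{levels}")
    g, h = _filters(decomp.wavelet_name)
    n = decomp.n
    v = decomp.approximation.copy() if keep_approximation else np.zeros(n)
    zero = np.zeros(n)
    for j in range(levels, 0, -1):
        stride = 2 ** (j - 1)
        w_j = decomp.details[j - 1] if j in keep_details else zero
        v_prev = np.zeros(n)
        for tap, (g_l, h_l) in enumerate(zip(g, h)):
            v_prev += h_l * np.roll(w_j, -stride * tap)
            v_prev += g_l * np.roll(v, -stride * tap)
        v = v_prev
    return UniformSignal(v, fs=decomp.fs, t0=decomp.t0)


def band_edges(fs: float, level: int, kind: str = "detail") -> BandEdges:
    """Nominal dyadic band of a detail level or of the final approximation."""
    if level < 1:
        raise ValueError("level must be >= 1")
    if not fs > 0:
        raise ValueError("fs must be positive")
    if kind == "detail":
        return BandEdges(fs / 2 ** (level + 1), fs / 2 ** level)
    if kind == "approximation":
        return BandEdges(0.0, fs / 2 ** (level + 1))
    raise ValueError(f"kind must be 'detail' or 'approximation', got {kind!r}")


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, the convention used when
    printing dyadic band edges (3.125 -> 3.12, 0.78125 -> 0.78)."""
    return math.floor(x * 100.0) / 100.0


def _warn_fs(fs: float, nominal: float, kind: str) -> None:
    if abs(fs - nominal) > 0.05 * nominal:
        warnings.warn(
            f"{kind} filter preset assumes fs near {nominal:g} Hz, got {fs:g} Hz; "
            "decomposition depth re-derived for this rate",
            stacklevel=3,
        )


def filter_ecg(signal: UniformSignal, wavelet: str = "sym4") -> UniformSignal:
    """ECG band filter: drop high-frequency details and the slow approximation.

    At 130 Hz this is a 10-level symlet-4 decomposition rejecting D1-D2
    (16.25-65 Hz) and A10 (< 0.064 Hz), reconstructing from D3..D10.  For
    other rates the depth and rejected levels are re-derived so the same
    absolute bands are rejected (with a warning).
    """
    _warn_fs(signal.fs, 130.0, "ECG")
    # depth: approximation upper edge fs/2^(L+1) must fall below 0.064 Hz
    levels = max(1, math.ceil(math.log2(signal.fs / ECG_APPROX_BELOW_HZ)) - 1)
    if levels > math.floor(math.log2(signal.n)):
        raise ValueError(
            f"signal too short for {levels} decomposition levels ({signal.n} samples)"
        )
    # reject details whose whole band sits at/above the high-frequency edge
    drop = {j for j in range(1, levels + 1)
            if band_edges(signal.fs, j).f_lo >= ECG_REJECT_ABOVE_HZ - 1e-9}
    keep = set(range(1, levels + 1)) - drop
    decomp = modwt(signal, wavelet=wavelet, levels=levels)
    return reconstruct(decomp, keep_details=keep, keep_approximation=False)


def filter_ppg(signal: UniformSignal, wavelet: str = "coif1") -> UniformSignal:
    """PPG band filter keeping only the pulse band (0.78-3.12 Hz at 25 Hz).

    At 25 Hz this is a 4-level coiflet-1 decomposition reconstructed from
    D3 and D4 only.  For other rates the kept levels are those whose dyadic
    bands overlap the same absolute pulse band (with a warning).
    """
    _warn_fs(signal.fs, 25.0, "PPG")
    lo, hi = PPG_BAND_HZ
    keep = set()
    j = 1
    while band_edges(signal.fs, j).f_lo > lo - 1e-9:
        e = band_edges(signal.fs, j)
        if e.f_lo < hi - 1e-9 and e.f_hi > lo + 1e-9:  # open-interval overlap
            keep.add(j)
        j += 1
    if not keep:
        raise ValueError(f"no dyadic band at fs={signal.fs} overlaps {lo:g}-{hi:g} Hz")
    levels = max(keep)
    if levels > math.floor(math.log2(signal.n)):
        raise ValueError(
            f"signal too short for {levels} decomposition levels ({signal.n} samples)"
        )
    decomp = modwt(signal, wavelet=wavelet, levels=levels)
    return reconstruct(decomp, keep_details=keep, keep_approximation=False)
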