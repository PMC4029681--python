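"""STFT front-end: windowing, one-sided spectra, analysis-band selection.

Each segment is multiplied by a periodic Hamming window and transformed with a
real FFT. Downstream features operate on the power spectrum P[k] = |X[k]|^2
over an analysis band that excludes heart sounds (concentrated below 60 Hz)
and the empty top of the spectrum; with a 512-point transform at 8 kHz the
default 60-950 Hz band spans 57 bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .audio_io import Recording, Segment, frame_segments

__all__ = ["SpectrumFrame", "BandSelection", "analyze_segment", "select_band", "stft_frames"]

DEFAULT_BAND = (60.0, 950.0)


@dataclass
class SpectrumFrame:
    """One segment's one-sided spectra (bins 0..N/2)."""

    m: int
    X: np.ndarray  # complex spectrum
    P: np.ndarray  # power spectrum |X|^2
    A: np.ndarray  # amplitude spectrum sqrt(P)
    Phi: np.ndarray | None  # phase spectrum in (-pi, pi], None unless requested
    bin_hz: float

    @property
    def n_fft(self) -> int:
        return 2 * (self.X.size - 1)


@dataclass(frozen=True)
class BandSelection:
    """Inclusive bin range [k_lo, k_hi] of the analysis band."""

    k_lo: int
    k_hi: int

    @property
    def n_bins(self) -> int:
        return self.k_hi - self.k_lo + 1

    @property
    def sl(self) -> slice:
        return slice(self.k_lo, self.k_hi + 1)


def analyze_segment(
    seg: Segment,
    window: str | np.ndarray = "hamming",
    need_phase: bool = False,
    sample_rate: int = 8_000,
) -> SpectrumFrame:
    """Window a segment and compute its one-sided DFT spectra.

    The phase spectrum is only materialized when ``need_phase`` is set (it is
    needed by the tonality feature alone, and costs an arctangent per bin on
    the DSP the cost model describes).
    """
    x = np.asarray(seg.samples, dtype=float)
    n = x.size
    if isinstance(window, str):
        w = get_window(window, n, fftbins=True)  # periodic variant, STFT convention
    else:
        w = np.asarray(window, dtype=float)
        if w.size != n:
            raise ValueError(f"window length {w.size} != segment length {n}")
    X = np.fft.rfft(x * w)
    P = X.real**2 + X.imag**2
    A = np.sqrt(P)
    Phi = np.angle(X) if need_phase else None
    return SpectrumFrame(m=seg.index, X=X, P=P, A=A, Phi=Phi, bin_hz=sample_rate / n)


def select_band(n_fft: int, bin_hz: float, f_lo: float, f_hi: float) -> BandSelection:
    """Map an [f_lo, f_hi] Hz band to inclusive one-sided bin indices.

    k_lo = ceil(f_lo / bin_hz), k_hi = floor(f_hi / bin_hz).
    """
    nyquist = bin_hz * (n_fft // 2)
    if not 0 <= f_lo < f_hi <= nyquist:
        raise ValueError(f"need 0 <= f_lo < f_hi <= Nyquist ({nyquist} Hz)")
    k_lo = math.ceil(f_lo / bin_hz)
    k_hi = math.floor(f_hi / bin_hz)
    if k_hi < k_lo:
        raise ValueError("selected band contains no bins")
    return BandSelection(k_lo=k_lo, k_hi=k_hi)


def stft_frames(
    rec: Recording,
    n: int = 512,
    overlap: float = 0.5,
    window: str = "hamming",
    need_phase: bool = False,
) -> list[SpectrumFrame]:
    """Frame a recording and analyze every segment."""
    return [
        analyze_segment(seg, window=window, need_phase=need_phase, sample_rate=rec.sample_rate)
        for seg in frame_segments(rec, n, overlap)
    ]
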