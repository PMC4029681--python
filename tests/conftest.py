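"""Shared fixtures: hand-built spectrum frames and small synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest

from wheezekit.audio_io import Recording
from wheezekit.spectral import BandSelection, SpectrumFrame


def make_frame(p: np.ndarray, m: int = 0, bin_hz: float = 15.625) -> SpectrumFrame:
    """Build a SpectrumFrame directly from a power spectrum (X from sqrt(P))."""
    p = np.asarray(p, dtype=float)
    a = np.sqrt(p)
    return SpectrumFrame(m=m, X=a.astype(complex), P=p, A=a, Phi=np.zeros_like(p), bin_hz=bin_hz)


@pytest.fixture
def band57() -> BandSelection:
    """The default analysis band at N=512 / 8 kHz: bins 4..60, 57 bins."""
    return BandSelection(k_lo=4, k_hi=60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tone_recording() -> Recording:
    """3 s of a steady 400 Hz tone at 8 kHz (plus a hint of noise floor)."""
    fs = 8000
    t = np.arange(3 * fs) / fs
    g = np.random.default_rng(7)
    x = np.sin(2 * np.pi * 400 * t) + 1e-4 * g.standard_normal(t.size)
    return Recording(samples=x / np.max(np.abs(x)), sample_rate=fs, id="tone400")


@pytest.fixture
def noise_recording() -> Recording:
    """3 s of white noise at 8 kHz."""
    g = np.random.default_rng(8)
    x = g.standard_normal(3 * 8000)
    return Recording(samples=x / np.max(np.abs(x)), sample_rate=8000, id="noise")
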