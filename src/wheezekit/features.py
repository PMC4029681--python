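"""Per-segment spectral features and temporal crest tracking.

A wheeze appears in the short-time power spectrum as a "crest": a flattened
band of elevated magnitude around a local maximum, persisting across segments
with only small frequency deviation. The features here quantify that picture:

* segment energy and its recent extrema (to gate out inter-respiratory pauses);
* a tonality index T -- the log2 ratio of prediction-error-weighted to raw
  segment energy, deeply negative for predictable (tonal) content and near
  zero for noise;
* strict local maxima of the power spectrum (candidate peaks);
* Shannon entropy of the normalized peak magnitudes, which drops when energy
  clusters into few peaks, and its segment-to-segment ratio;
* two crest acceptance models (low-order moments of the peak's surrounding
  band; energy of the crest vs. its annular surroundings);
* greedy nearest-neighbour tracking of crest frequencies through time, with
  per-lag deviation thresholds defining continuity.

All divisions and logarithms are guarded by EPS; the tonality index is clamped
to [T_FLOOR, -T_FLOOR].
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .spectral import BandSelection, SpectrumFrame

__all__ = [
    "EPS",
    "T_FLOOR",
    "RATIO_UNDEFINED",
    "EnergyHistory",
    "TonalityState",
    "PeakSet",
    "CrestSet",
    "CrestTrack",
    "EntropyPair",
    "segment_energy",
    "tonal_index",
    "find_spectral_peaks",
    "peak_entropy",
    "entropy_ratio",
    "detect_crests_moments",
    "detect_crests_energy",
    "update_crest_tracks",
]

EPS = 1e-12
T_FLOOR = -30.0
#: sentinel for an entropy ratio with a (near-)zero denominator; classifiers
#: treat it as "no transition".
RATIO_UNDEFINED = float("nan")


class EnergyHistory:
    """Ring buffer of the last ``m_e`` segment energies.

    ``m_e`` should cover at least one respiratory cycle so that the stored
    extrema always contain both a pause (minimum) and a breath (maximum);
    the default used by the classifiers is 156 segments (about 5 s at the
    32 ms hop).
    """

    def __init__(self, m_e: int = 156):
        if m_e < 1:
            raise ValueError("history length must be >= 1")
        self.m_e = m_e
        self._buf: deque[float] = deque(maxlen=m_e)

    def push(self, energy: float) -> None:
        self._buf.append(float(energy))

    def __len__(self) -> int:
        return len(self._buf)

    def bounds(self) -> tuple[float, float]:
        """(E_min, E_max) over the stored window."""
        if not self._buf:
            raise RuntimeError("energy history is empty")
        return min(self._buf), max(self._buf)


def segment_energy(frame: SpectrumFrame, band: BandSelection) -> float:
    """Sum of the power spectrum over the analysis band."""
    if band.k_hi >= frame.P.size:
        raise ValueError("band exceeds spectrum length")
    return float(np.sum(frame.P[band.sl]))


@dataclass
class TonalityState:
    """Amplitude/phase spectra of the two preceding segments, over the band."""

    a1: np.ndarray | None = None  # segment m-1
    phi1: np.ndarray | None = None
    a2: np.ndarray | None = None  # segment m-2
    phi2: np.ndarray | None = None

    @property
    def primed(self) -> bool:
        return self.a2 is not None

    def push(self, a: np.ndarray, phi: np.ndarray) -> None:
        self.a2, self.phi2 = self.a1, self.phi1
        self.a1, self.phi1 = np.array(a, dtype=float), np.array(phi, dtype=float)


def tonal_index(frame: SpectrumFrame, state: TonalityState, band: BandSelection) -> float:
    """Tonality index T of the current segment (does not mutate ``state``).

    Amplitude and phase are linearly extrapolated from the two previous
    segments (A_hat = 2A[m-1] - A[m-2], likewise for phase); the per-bin
    unpredictability weight is

        W = sqrt((Re X - Re X_hat)^2 + (Im X - Im X_hat)^2) / (A + |A_hat|)

    and T = log2(E_w / E) with E_w = sum(W * P). A perfectly predictable
    (stationary tonal) segment gives W = 0 everywhere and T at the clamp
    floor; noise gives T near zero.
    """
    if not state.primed:
        raise RuntimeError("tonality needs two prior segments")
    if frame.Phi is None:
        raise ValueError("frame was analyzed without phase")
    sl = band.sl
    a, phi = frame.A[sl], frame.Phi[sl]
    p = frame.P[sl]
    a_hat = 2.0 * state.a1 - state.a2
    phi_hat = 2.0 * state.phi1 - state.phi2
    re_hat = a_hat * np.cos(phi_hat)
    im_hat = a_hat * np.sin(phi_hat)
    re = a * np.cos(phi)
    im = a * np.sin(phi)
    w = np.sqrt((re - re_hat) ** 2 + (im - im_hat) ** 2) / (a + np.abs(a_hat) + EPS)
    e = float(np.sum(p))
    e_w = float(np.sum(w * p))
    t = float(np.log2((e_w + EPS) / (e + EPS)))
    return float(np.clip(t, T_FLOOR, -T_FLOOR))


@dataclass
class PeakSet:
    """Strict local maxima of the in-band power spectrum, ascending bins."""

    k_peak: np.ndarray  # absolute bin indices
    p_peak: np.ndarray  # magnitudes P[k]

    @property
    def n_p(self) -> int:
        return int(self.k_peak.size)


@dataclass
class CrestSet:
    """Accepted crest peaks; always a subset of the PeakSet it came from."""

    k_crest: np.ndarray
    p_crest: np.ndarray

    @property
    def n_c(self) -> int:
        return int(self.k_crest.size)


def find_spectral_peaks(frame: SpectrumFrame, band: BandSelection) -> PeakSet:
    """Strict local maxima P[k-1] < P[k] > P[k+1] inside the band.

    Band-edge bins cannot be peaks (no two-sided neighbourhood).
    """
    if band.n_bins < 3:
        raise ValueError("band must span at least 3 bins")
    p = frame.P[band.sl]
    interior = np.arange(1, p.size - 1)
    mask = (p[interior] > p[interior - 1]) & (p[interior] > p[interior + 1])
    k = interior[mask] + band.k_lo
    return PeakSet(k_peak=k, p_peak=frame.P[k])


@dataclass
class EntropyPair:
    en_current: float
    en_previous: float


def peak_entropy(peaks: PeakSet) -> float:
    """Shannon entropy (bits) of the normalized peak magnitudes.

    Zero peaks (or zero total magnitude) is defined as entropy 0: a spectrum
    with no structure to distribute mass over.
    """
    if peaks.n_p == 0:
        return 0.0
    total = float(np.sum(peaks.p_peak))
    if total <= EPS:
        return 0.0
    p = peaks.p_peak / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def entropy_ratio(pair: EntropyPair) -> float:
    """En[m] / En[m-1]; RATIO_UNDEFINED (NaN) when the previous entropy is ~0."""
    if pair.en_previous < EPS:
        return RATIO_UNDEFINED
    return pair.en_current / pair.en_previous


def _crest_bins(k: int, b_crest: int, band: BandSelection) -> slice:
    """Inclusive bins [k - b_crest/2, k + b_crest/2], clipped to the band."""
    half = b_crest // 2
    lo = max(k - half, band.k_lo)
    hi = min(k + half, band.k_hi)
    return slice(lo, hi + 1)


def detect_crests_moments(
    frame: SpectrumFrame,
    peaks: PeakSet,
    band: BandSelection,
    b_crest: int = 6,
    c_m: float = 1.5,
    c_s: float = 1.0,
) -> CrestSet:
    """Moment-model crest acceptance.

    A peak is a crest peak when its magnitude exceeds
    ``c_m * mean + c_s * stdev`` of the power values in its surrounding band
    of ``b_crest + 1`` bins (population standard deviation, matching
    fixed-point DSP statistics routines).
    """
    if b_crest < 2 or b_crest % 2:
        raise ValueError("b_crest must be even and >= 2")
    keep = []
    for i in range(peaks.n_p):
        k = int(peaks.k_peak[i])
        vals = frame.P[_crest_bins(k, b_crest, band)]
        thresh = c_m * float(np.mean(vals)) + c_s * float(np.std(vals))
        if peaks.p_peak[i] > thresh:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return CrestSet(k_crest=peaks.k_peak[idx], p_crest=peaks.p_peak[idx])


def detect_crests_energy(
    frame: SpectrumFrame,
    peaks: PeakSet,
    band: BandSelection,
    b_crest: int = 2,
    b_narrow_hz: float = 80.0,
    b_wide_hz: float = 120.0,
    c_narrow: float = 1.2,
    c_wide: float = 1.5,
) -> CrestSet:
    """Energy-model crest acceptance.

    The crest energy (power summed over the ``b_crest + 1`` crest bins) is
    compared against the energy of two annular surroundings -- the narrow and
    wide bands, measured in Hz, *excluding* the crest bins. A peak is accepted
    when both ratios exceed their thresholds; if a surrounding holds no energy
    at all (a pure tone on silence) the peak is accepted outright.
    """
    half_n = round(b_narrow_hz / 2.0 / frame.bin_hz)
    half_w = round(b_wide_hz / 2.0 / frame.bin_hz)
    if not b_crest // 2 < half_n < half_w:
        raise ValueError("need b_crest/2 < narrow half-width < wide half-width in bins")
    keep = []
    for i in range(peaks.n_p):
        k = int(peaks.k_peak[i])
        crest = _crest_bins(k, b_crest, band)
        e_crest = float(np.sum(frame.P[crest]))
        accept = True
        for half, c in ((half_n, c_narrow), (half_w, c_wide)):
            lo = max(k - half, band.k_lo)
            hi = min(k + half, band.k_hi)
            e_annulus = float(np.sum(frame.P[lo : hi + 1])) - e_crest
            if e_annulus <= EPS:
                continue  # silent surroundings: tone on silence, keep
            if e_crest / e_annulus <= c:
                accept = False
                break
        if accept:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return CrestSet(k_crest=peaks.k_peak[idx], p_crest=peaks.p_peak[idx])


@dataclass
class CrestTrack:
    """A crest followed through time.

    ``bins`` stores the most recent peak bins (current first is last element);
    ``duration`` counts segments the track has been alive.
    """

    bins: deque = field(default_factory=lambda: deque(maxlen=8))
    duration: int = 1

    @property
    def current_bin(self) -> int:
        return self.bins[-1]

    def deviations(self, m_cont: int) -> list[int]:
        """|k[m] - k[m-j]| for j = 1 .. min(m_cont, duration-1)."""
        cur = self.bins[-1]
        n_lags = min(m_cont, self.duration - 1, len(self.bins) - 1)
        return [abs(cur - self.bins[-1 - j]) for j in range(1, n_lags + 1)]

    def is_continuous(self, m_cont: int, c_cont: list[float]) -> bool:
        devs = self.deviations(m_cont)
        return all(d < c_cont[j] for j, d in enumerate(devs))


def update_crest_tracks(
    tracks: list[CrestTrack],
    crests: CrestSet,
    m_cont: int,
    c_cont: list[float],
) -> list[CrestTrack]:
    """Advance tracks by one segment with the current crest set.

    Crest-to-track assignment is greedy nearest-neighbour on |delta bin|,
    ties broken by lower crest frequency then lower track frequency; a crest
    may only join a track within ``c_cont[0]`` bins (beyond that it is a new
    component, not a drifted one). Matched tracks extend, unmatched crests
    spawn fresh tracks, unmatched tracks die.
    """
    if len(c_cont) < m_cont:
        raise ValueError("need one continuity threshold per lag")
    pairs = sorted(
        (abs(int(kc) - tr.current_bin), int(kc), tr.current_bin, ci, ti)
        for ci, kc in enumerate(crests.k_crest)
        for ti, tr in enumerate(tracks)
    )
    gate = c_cont[0]
    taken_crests: set[int] = set()
    taken_tracks: set[int] = set()
    new_tracks: list[CrestTrack] = []
    for dist, kc, _kt, ci, ti in pairs:
        if dist >= gate or ci in taken_crests or ti in taken_tracks:
            continue
        tr = tracks[ti]
        if tr.bins.maxlen != m_cont + 1:
            tr.bins = deque(tr.bins, maxlen=m_cont + 1)
        tr.bins.append(kc)
        tr.duration += 1
        new_tracks.append(tr)
        taken_crests.add(ci)
        taken_tracks.add(ti)
    for ci, kc in enumerate(crests.k_crest):
        if ci not in taken_crests:
            t = CrestTrack(bins=deque([int(kc)], maxlen=m_cont + 1), duration=1)
            new_tracks.append(t)
    new_tracks.sort(key=lambda t: t.current_bin)
    return new_tracks
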