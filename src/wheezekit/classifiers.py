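"""The four per-segment decision trees.

All four share the same root: an energy gate that compares the current segment
energy against the recent energy extrema and declares inter-respiratory pauses
normal without any further work (early termination). The branches differ:

* Algorithm 1 -- crest tracking with the moments crest model;
* Algorithm 2 -- crest tracking with the energy crest model;
* Algorithm 3 -- tonality tracking (runs of segments with T below C_T);
* Algorithm 4 -- entropy-change detection (two-sided test on the ratio of
  successive peak entropies).

Classification is strictly streaming: one :class:`SegmentLabel` per
:class:`~wheezekit.spectral.SpectrumFrame`, with all temporal state carried by
:class:`ClassifierState`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .features import (
    EPS,
    CrestSet,
    CrestTrack,
    EnergyHistory,
    EntropyPair,
    PeakSet,
    TonalityState,
    detect_crests_energy,
    detect_crests_moments,
    entropy_ratio,
    find_spectral_peaks,
    peak_entropy,
    segment_energy,
    tonal_index,
    update_crest_tracks,
)
from .spectral import BandSelection, SpectrumFrame

__all__ = [
    "ClassifierConfig",
    "ClassifierState",
    "SegmentLabel",
    "energy_gate",
    "classify_segment",
    "classify_frames",
    "load_config",
    "save_config",
]

WHEEZE = "WHEEZE"
NORMAL = "NORMAL"


@dataclass
class SegmentLabel:
    value: str  # WHEEZE or NORMAL
    gate: str  # "active" or "pause"

    @property
    def is_wheeze(self) -> bool:
        return self.value == WHEEZE


@dataclass
class ClassifierConfig:
    """Every tunable threshold of the four decision trees.

    Durations are in segments (32 ms at the default grid), bandwidths for the
    moments model in bins, for the energy model in Hz. ``m_dur_min`` is tied
    to ``m_cont``: a crest only counts as wheezing once it has existed long
    enough for all continuity lags to be checked.
    """

    algorithm: int = 1
    # segment grid
    n_fft: int = 512
    overlap: float = 0.5
    sample_rate: int = 8_000
    window: str = "hamming"
    band_lo_hz: float = 60.0
    band_hi_hz: float = 950.0
    # energy gate
    m_e: int = 156
    c_pause: float = 0.1
    # algorithm 1: moments crest model
    b_crest: int = 6
    c_m: float = 1.5
    c_s: float = 1.0
    # algorithm 2: energy crest model
    b_crest_energy: int = 2
    b_narrow_hz: float = 80.0
    b_wide_hz: float = 120.0
    c_narrow: float = 1.2
    c_wide: float = 1.5
    # algorithms 1-2: counting / continuity / duration
    c_crests: int = 7
    m_cont: int = 4
    c_cont: list[float] = field(default_factory=lambda: [3.0, 3.0, 3.0, 3.0])
    m_dur_max: int = 150
    # algorithm 3
    c_t: float = -2.0
    # algorithm 4
    c_ent: float = 2.0

    def __post_init__(self) -> None:
        if self.algorithm not in (1, 2, 3, 4):
            raise ValueError("algorithm must be 1, 2, 3 or 4")
        if not 0 <= self.c_pause <= 1:
            raise ValueError("c_pause must lie in [0, 1]")
        if len(self.c_cont) < self.m_cont:
            raise ValueError("c_cont must provide one threshold per continuity lag")
        if self.m_dur_max <= self.m_dur_min:
            raise ValueError("m_dur_max must exceed m_dur_min")
        if self.c_ent < 1:
            raise ValueError("c_ent must be >= 1")

    @property
    def m_dur_min(self) -> int:
        return self.m_cont

    @property
    def needs_phase(self) -> bool:
        return self.algorithm == 3

    def with_params(self, **kwargs) -> "ClassifierConfig":
        return replace(self, **kwargs)


def save_config(path: str | Path, cfg: ClassifierConfig) -> None:
    path = Path(path)
    data = asdict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> ClassifierConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ClassifierConfig(**data)


def energy_gate(e: float, e_min: float, e_max: float, c_pause: float) -> str:
    """Decision-tree root: ``active`` unless the segment sits near the stored
    energy minimum (an inter-respiratory pause).

    Active iff E > E_min + c_pause * (E_max - E_min). A degenerate history
    fails open to ``active``: either E_min == E_max, or the stored dynamic
    range is a negligible fraction of the level (a steady signal has no
    pauses to skip; the rule is meant for the orders-of-magnitude drop
    between breath sound and inter-respiratory silence).
    """
    if e_min > e_max:
        raise ValueError("e_min must not exceed e_max")
    if e_max - e_min <= EPS + 1e-3 * e_max:
        return "active"
    return "active" if e > e_min + c_pause * (e_max - e_min) else "pause"


@dataclass
class ClassifierState:
    """All temporal state of one streaming classifier."""

    cfg: ClassifierConfig
    band: BandSelection
    energy: EnergyHistory = field(init=False)
    tracks: list[CrestTrack] = field(default_factory=list)
    tonality: TonalityState = field(default_factory=TonalityState)
    tonal_run: int = 0  # delta-m_tonal
    prev_entropy: float | None = None

    def __post_init__(self) -> None:
        self.energy = EnergyHistory(self.cfg.m_e)


def _classify_crest_tracking(
    state: ClassifierState, frame: SpectrumFrame, peaks: PeakSet
) -> str:
    cfg = state.cfg
    if cfg.algorithm == 1:
        crests = detect_crests_moments(
            frame, peaks, state.band, cfg.b_crest, cfg.c_m, cfg.c_s
        )
    else:
        crests = detect_crests_energy(
            frame,
            peaks,
            state.band,
            cfg.b_crest_energy,
            cfg.b_narrow_hz,
            cfg.b_wide_hz,
            cfg.c_narrow,
            cfg.c_wide,
        )
    # count gate: a wheeze is one to a few harmonic components, not a comb
    if not 1 <= crests.n_c <= cfg.c_crests:
        crests = CrestSet(k_crest=crests.k_crest[:0], p_crest=crests.p_crest[:0])
        state.tracks = update_crest_tracks(state.tracks, crests, cfg.m_cont, cfg.c_cont)
        return NORMAL
    state.tracks = update_crest_tracks(state.tracks, crests, cfg.m_cont, cfg.c_cont)
    for tr in state.tracks:
        if (
            cfg.m_dur_min <= tr.duration <= cfg.m_dur_max
            and tr.is_continuous(cfg.m_cont, cfg.c_cont)
        ):
            return WHEEZE
    return NORMAL


def _classify_tonality(state: ClassifierState, frame: SpectrumFrame) -> str:
    cfg = state.cfg
    if not state.tonality.primed:
        return NORMAL
    t = tonal_index(frame, state.tonality, state.band)
    if t < cfg.c_t:
        state.tonal_run += 1
    else:
        state.tonal_run = 0
    if state.tonal_run and cfg.m_dur_min <= state.tonal_run <= cfg.m_dur_max:
        return WHEEZE
    return NORMAL


def _classify_entropy(state: ClassifierState, frame: SpectrumFrame, peaks: PeakSet) -> str:
    cfg = state.cfg
    en = peak_entropy(peaks)
    prev = state.prev_entropy
    state.prev_entropy = en
    if prev is None:
        return NORMAL
    ratio = entropy_ratio(EntropyPair(en_current=en, en_previous=prev))
    if ratio != ratio:  # RATIO_UNDEFINED sentinel (NaN): no transition
        return NORMAL
    change = max(ratio, 1.0 / ratio) if ratio > EPS else float("inf")
    return WHEEZE if change > cfg.c_ent else NORMAL


def classify_segment(state: ClassifierState, frame: SpectrumFrame) -> SegmentLabel:
    """Run one segment through the decision tree of ``state.cfg.algorithm``."""
    cfg = state.cfg
    e = segment_energy(frame, state.band)
    state.energy.push(e)
    e_min, e_max = state.energy.bounds()
    gate = energy_gate(e, e_min, e_max, cfg.c_pause)

    # Algorithm 3 keeps its two-segment spectral history across pauses so the
    # predictor is primed the moment the gate re-opens.
    if cfg.algorithm == 3:
        primed_frame = state.tonality.primed
        if gate == "pause":
            state.tonality.push(frame.A[state.band.sl], frame.Phi[state.band.sl])
            state.tonal_run = 0
            return SegmentLabel(NORMAL, gate)
        value = _classify_tonality(state, frame) if primed_frame else NORMAL
        state.tonality.push(frame.A[state.band.sl], frame.Phi[state.band.sl])
        return SegmentLabel(value, gate)

    if gate == "pause":
        # early termination: no feature extraction; live crest tracks die
        if cfg.algorithm in (1, 2):
            empty = CrestSet(
                k_crest=np.asarray([], dtype=int), p_crest=np.asarray([], dtype=float)
            )
            state.tracks = update_crest_tracks(state.tracks, empty, cfg.m_cont, cfg.c_cont)
        return SegmentLabel(NORMAL, gate)

    peaks = find_spectral_peaks(frame, state.band)
    if cfg.algorithm in (1, 2):
        value = _classify_crest_tracking(state, frame, peaks)
    else:
        value = _classify_entropy(state, frame, peaks)
    return SegmentLabel(value, gate)


def classify_frames(
    frames: list[SpectrumFrame], cfg: ClassifierConfig, band: BandSelection
) -> list[SegmentLabel]:
    """Classify a whole frame stream with fresh state."""
    state = ClassifierState(cfg=cfg, band=band)
    return [classify_segment(state, f) for f in frames]
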