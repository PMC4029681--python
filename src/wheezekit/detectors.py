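"""Scikit-learn style estimator facade over the four decision trees.

Each detector is a :class:`~sklearn.base.BaseEstimator`: constructor
parameters are the non-trainable grid settings plus the trainable thresholds'
defaults, ``fit`` runs the grid-search threshold training on a list of
``(Recording, Annotation)`` pairs (setting ``config_``, ``auc_max_`` and
``roc_points_``), and ``predict`` maps a recording to its boolean per-segment
wheeze labels. The estimators compose with ``sklearn.base.clone`` and
``get_params``/``set_params``; the functional API in
:mod:`wheezekit.classifiers` and :mod:`wheezekit.evaluation` stays available
underneath.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .audio_io import Annotation, Recording, frame_segments
from .classifiers import ClassifierConfig, classify_frames
from .evaluation import (
    default_grid,
    grid_search_train,
    prepare_recording,
)
from .spectral import select_band, stft_frames

__all__ = [
    "CrestMomentsDetector",
    "CrestEnergyDetector",
    "TonalityDetector",
    "EntropyRatioDetector",
    "make_detector",
]


class _BaseWheezeDetector(BaseEstimator):
    """Shared fit/predict plumbing; subclasses fix the algorithm id."""

    _algorithm: int = 0

    def __init__(
        self,
        n_fft: int = 512,
        overlap: float = 0.5,
        band_lo_hz: float = 60.0,
        band_hi_hz: float = 950.0,
        m_e: int = 156,
        c_pause: float = 0.1,
        grid: dict | None = None,
    ):
        self.n_fft = n_fft
        self.overlap = overlap
        self.band_lo_hz = band_lo_hz
        self.band_hi_hz = band_hi_hz
        self.m_e = m_e
        self.c_pause = c_pause
        self.grid = grid

    def _extra_config(self) -> dict:
        return {}

    def base_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            algorithm=self._algorithm,
            n_fft=self.n_fft,
            overlap=self.overlap,
            band_lo_hz=self.band_lo_hz,
            band_hi_hz=self.band_hi_hz,
            m_e=self.m_e,
            c_pause=self.c_pause,
            **self._extra_config(),
        )

    def fit(self, X: list[tuple[Recording, Annotation]], y=None):
        """Grid-search the trainable thresholds on annotated recordings.

        ``X`` is a list of ``(Recording, Annotation)`` pairs; ``y`` is unused
        (labels live in the annotations) and accepted for API compatibility.
        """
        if not X:
            raise ValueError("fit requires at least one annotated recording")
        base = self.base_config()
        prepared = [prepare_recording(rec, annot, base) for rec, annot in X]
        grid = self.grid if self.grid is not None else default_grid(self._algorithm)
        result = grid_search_train(prepared, base, grid)
        self.config_ = result.config
        self.auc_max_ = result.auc_max
        self.roc_points_ = result.roc_points
        return self

    def predict(self, recording: Recording) -> np.ndarray:
        """Boolean per-segment wheeze labels for one recording."""
        check_is_fitted(self, "config_")
        cfg = self.config_
        frames = stft_frames(
            recording, cfg.n_fft, cfg.overlap, window=cfg.window,
            need_phase=cfg.needs_phase,
        )
        band = select_band(
            cfg.n_fft, recording.sample_rate / cfg.n_fft, cfg.band_lo_hz, cfg.band_hi_hz
        )
        labels = classify_frames(frames, cfg, band)
        return np.asarray([lab.is_wheeze for lab in labels])

    def segment_times(self, recording: Recording) -> np.ndarray:
        """Center time (s) of each segment ``predict`` labels."""
        segs = frame_segments(recording, self.n_fft, self.overlap)
        half = self.n_fft / 2 / recording.sample_rate
        return np.asarray([s.start_time + half for s in segs])


class CrestMomentsDetector(_BaseWheezeDetector):
    """Crest tracking with the moments crest model (algorithm 1).

    A peak is a crest when it exceeds ``c_m * mean + c_s * std`` of its
    surrounding ``b_crest + 1``-bin band; crests tracked through time must be
    continuous for ``m_cont`` lags and last between the duration bounds.
    """

    _algorithm = 1

    def __init__(
        self,
        n_fft: int = 512,
        overlap: float = 0.5,
        band_lo_hz: float = 60.0,
        band_hi_hz: float = 950.0,
        m_e: int = 156,
        c_pause: float = 0.1,
        grid: dict | None = None,
        b_crest: int = 6,
        c_m: float = 1.5,
        c_s: float = 1.0,
        c_crests: int = 7,
        m_cont: int = 4,
        m_dur_max: int = 150,
    ):
        super().__init__(n_fft, overlap, band_lo_hz, band_hi_hz, m_e, c_pause, grid)
        self.b_crest = b_crest
        self.c_m = c_m
        self.c_s = c_s
        self.c_crests = c_crests
        self.m_cont = m_cont
        self.m_dur_max = m_dur_max

    def _extra_config(self) -> dict:
        return {
            "b_crest": self.b_crest,
            "c_m": self.c_m,
            "c_s": self.c_s,
            "c_crests": self.c_crests,
            "m_cont": self.m_cont,
            "c_cont": [3.0] * self.m_cont,
            "m_dur_max": self.m_dur_max,
        }


class CrestEnergyDetector(_BaseWheezeDetector):
    """Crest tracking with the energy crest model (algorithm 2).

    A peak is a crest when the crest-band energy dominates both its narrow
    and wide annular surroundings by the trained ratios.
    """

    _algorithm = 2

    def __init__(
        self,
        n_fft: int = 512,
        overlap: float = 0.5,
        band_lo_hz: float = 60.0,
        band_hi_hz: float = 950.0,
        m_e: int = 156,
        c_pause: float = 0.1,
        grid: dict | None = None,
        b_crest_energy: int = 2,
        b_narrow_hz: float = 80.0,
        b_wide_hz: float = 120.0,
        c_narrow: float = 1.2,
        c_wide: float = 1.5,
        c_crests: int = 7,
        m_cont: int = 4,
        m_dur_max: int = 150,
    ):
        super().__init__(n_fft, overlap, band_lo_hz, band_hi_hz, m_e, c_pause, grid)
        self.b_crest_energy = b_crest_energy
        self.b_narrow_hz = b_narrow_hz
        self.b_wide_hz = b_wide_hz
        self.c_narrow = c_narrow
        self.c_wide = c_wide
        self.c_crests = c_crests
        self.m_cont = m_cont
        self.m_dur_max = m_dur_max

    def _extra_config(self) -> dict:
        return {
            "b_crest_energy": self.b_crest_energy,
            "b_narrow_hz": self.b_narrow_hz,
            "b_wide_hz": self.b_wide_hz,
            "c_narrow": self.c_narrow,
            "c_wide": self.c_wide,
            "c_crests": self.c_crests,
            "m_cont": self.m_cont,
            "c_cont": [3.0] * self.m_cont,
            "m_dur_max": self.m_dur_max,
        }


class TonalityDetector(_BaseWheezeDetector):
    """Tonality-run tracking (algorithm 3): wheeze when the tonality index
    stays below ``c_t`` for between ``m_cont`` and ``m_dur_max`` segments."""

    _algorithm = 3

    def __init__(
        self,
        n_fft: int = 512,
        overlap: float = 0.5,
        band_lo_hz: float = 60.0,
        band_hi_hz: float = 950.0,
        m_e: int = 156,
        c_pause: float = 0.1,
        grid: dict | None = None,
        c_t: float = -2.0,
        m_cont: int = 4,
        m_dur_max: int = 150,
    ):
        super().__init__(n_fft, overlap, band_lo_hz, band_hi_hz, m_e, c_pause, grid)
        self.c_t = c_t
        self.m_cont = m_cont
        self.m_dur_max = m_dur_max

    def _extra_config(self) -> dict:
        return {
            "c_t": self.c_t,
            "m_cont": self.m_cont,
            "c_cont": [3.0] * self.m_cont,
            "m_dur_max": self.m_dur_max,
        }


class EntropyRatioDetector(_BaseWheezeDetector):
    """Entropy-change detection (algorithm 4): flags segments where the
    peak-entropy ratio to the previous segment departs from 1 by more than
    ``c_ent`` in either direction (onset or offset of clustering)."""

    _algorithm = 4

    def __init__(
        self,
        n_fft: int = 512,
        overlap: float = 0.5,
        band_lo_hz: float = 60.0,
        band_hi_hz: float = 950.0,
        m_e: int = 156,
        c_pause: float = 0.1,
        grid: dict | None = None,
        c_ent: float = 2.0,
    ):
        super().__init__(n_fft, overlap, band_lo_hz, band_hi_hz, m_e, c_pause, grid)
        self.c_ent = c_ent

    def _extra_config(self) -> dict:
        return {"c_ent": self.c_ent}


_DETECTORS = {
    1: CrestMomentsDetector,
    2: CrestEnergyDetector,
    3: TonalityDetector,
    4: EntropyRatioDetector,
}


def make_detector(algorithm: int, **kwargs) -> _BaseWheezeDetector:
    """Instantiate the detector class for an algorithm id (1-4)."""
    try:
        cls = _DETECTORS[algorithm]
    except KeyError:
        raise ValueError("algorithm must be 1, 2, 3 or 4") from None
    return cls(**kwargs)
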