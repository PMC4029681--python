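"""Scoring, grid-search threshold training, leave-one-out protocol.

Two scoring scenarios are supported:

* **duration tracking** (segment-wise): every analysis segment is a sample;
  its reference class is the annotation label at the segment's center time.
* **event detection** (phase-wise): every inspiratory/expiratory phase is a
  sample; a phase overlapping a wheeze interval is a reference positive, and
  it is scored true positive as soon as at least one of its segments is
  classified positive (analogously, any positive segment inside a reference
  negative phase makes it a false positive).

Thresholds are trained by exhaustive grid search maximizing the product
SE * SP of pooled sensitivity and specificity over the training recordings --
the point of the ROC cloud closest to the ideal corner under the product
objective. Ties resolve to the first grid point in deterministic lexicographic
order. Leave-one-out holds each recording out in turn and pools the held-out
confusion counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .audio_io import Annotation, Recording, frame_segments
from .classifiers import ClassifierConfig, classify_frames
from .spectral import BandSelection, select_band, stft_frames

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "TrainingResult",
    "PreparedRecording",
    "prepare_recording",
    "reference_segment_labels",
    "score_segmentwise",
    "score_phasewise",
    "grid_search_train",
    "leave_one_out",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    """Sensitivity / specificity / accuracy as fractions; None when undefined."""

    se: float | None
    sp: float | None
    ac: float | None

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "Metrics":
        se = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
        sp = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
        ac = (c.tp + c.tn) / c.total if c.total > 0 else None
        return cls(se=se, sp=sp, ac=ac)

    @property
    def auc_product(self) -> float:
        """SE * SP objective; an undefined component contributes 0."""
        return (self.se or 0.0) * (self.sp or 0.0)


@dataclass
class TrainingResult:
    config: ClassifierConfig
    roc_points: list[tuple[float, float]]  # (FPR, TPR) per grid point
    auc_max: float


@dataclass
class PreparedRecording:
    """A recording with its STFT frames precomputed for repeated evaluation."""

    recording: Recording
    annotation: Annotation
    frames: list
    band: BandSelection
    centers: np.ndarray  # segment center times, seconds
    id: str = ""


def prepare_recording(
    rec: Recording, annot: Annotation, cfg: ClassifierConfig
) -> PreparedRecording:
    segs = frame_segments(rec, cfg.n_fft, cfg.overlap)
    frames = stft_frames(
        rec, cfg.n_fft, cfg.overlap, window=cfg.window, need_phase=cfg.needs_phase
    )
    half = cfg.n_fft / 2 / rec.sample_rate
    centers = np.asarray([s.start_time + half for s in segs])
    band = select_band(cfg.n_fft, rec.sample_rate / cfg.n_fft, cfg.band_lo_hz, cfg.band_hi_hz)
    return PreparedRecording(
        recording=rec, annotation=annot, frames=frames, band=band,
        centers=centers, id=rec.id,
    )


def reference_segment_labels(annot: Annotation, centers: np.ndarray) -> np.ndarray:
    """Reference class per segment: True (wheeze) iff its center falls in a W interval."""
    ref = np.zeros(centers.size, dtype=bool)
    for s, e in annot.wheeze_intervals():
        ref |= (centers >= s) & (centers < e)
    return ref


def score_segmentwise(
    predictions: np.ndarray, annot: Annotation, centers: np.ndarray
) -> tuple[ConfusionCounts, Metrics]:
    """Segment-wise confusion counts and metrics (duration-tracking scenario)."""
    pred = np.asarray(predictions, dtype=bool)
    if pred.size != centers.size:
        raise ValueError("predictions and segment grid differ in length")
    ref = reference_segment_labels(annot, centers)
    counts = ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )
    return counts, Metrics.from_counts(counts)


def score_phasewise(
    predictions: np.ndarray, annot: Annotation, centers: np.ndarray
) -> tuple[ConfusionCounts, Metrics]:
    """Phase-wise confusion counts and metrics (event-detection scenario).

    Only inspiratory/expiratory phases are scored (pauses carry no breath
    sound to classify). A phase is a reference positive when it overlaps any
    annotated wheeze interval.
    """
    pred = np.asarray(predictions, dtype=bool)
    if pred.size != centers.size:
        raise ValueError("predictions and segment grid differ in length")
    resp_phases = [(s, e) for s, e, name in annot.phases if name in ("insp", "exp")]
    if not resp_phases:
        raise ValueError("annotation carries no respiratory phases")
    wheeze = annot.wheeze_intervals()
    counts = ConfusionCounts()
    for s, e in resp_phases:
        ref_pos = any(ws < e and we > s for ws, we in wheeze)
        inside = (centers >= s) & (centers < e)
        hit = bool(np.any(pred & inside))
        if ref_pos:
            counts.tp += hit
            counts.fn += not hit
        else:
            counts.fp += hit
            counts.tn += not hit
    return counts, Metrics.from_counts(counts)


def _grid_configs(base: ClassifierConfig, grid: dict[str, list]) -> list[ClassifierConfig]:
    if not grid:
        raise ValueError("empty grid")
    names = list(grid)
    configs = []
    for values in itertools.product(*(grid[n] for n in names)):
        configs.append(base.with_params(**dict(zip(names, values))))
    return configs


def _predict(prep: PreparedRecording, cfg: ClassifierConfig) -> np.ndarray:
    labels = classify_frames(prep.frames, cfg, prep.band)
    return np.asarray([lab.is_wheeze for lab in labels])


def default_grid(algorithm: int) -> dict[str, list]:
    """A modest, deterministic threshold grid per algorithm."""
    if algorithm == 1:
        return {"c_m": [1.0, 1.5, 2.0, 3.0], "c_s": [0.5, 1.0, 2.0, 3.0]}
    if algorithm == 2:
        return {"c_narrow": [0.8, 1.2, 1.6, 2.4], "c_wide": [1.0, 1.5, 2.0, 3.0]}
    if algorithm == 3:
        return {"c_t": [-6.0, -4.0, -3.0, -2.0, -1.5, -1.0]}
    return {"c_ent": [1.2, 1.4, 1.6, 1.8, 2.0, 2.5, 3.0, 3.5, 4.0]}


def grid_search_train(
    train: list[PreparedRecording],
    base_cfg: ClassifierConfig,
    grid: dict[str, list] | None = None,
    objective: str = "segment",
) -> TrainingResult:
    """Exhaustive grid search maximizing pooled SE * SP over the training set."""
    grid = grid if grid is not None else default_grid(base_cfg.algorithm)
    configs = _grid_configs(base_cfg, grid)
    scorer = score_segmentwise if objective == "segment" else score_phasewise
    best_i, best_auc = 0, -1.0
    roc: list[tuple[float, float]] = []
    for i, cfg in enumerate(configs):
        pooled = ConfusionCounts()
        for prep in train:
            counts, _ = scorer(_predict(prep, cfg), prep.annotation, prep.centers)
            pooled = pooled + counts
        m = Metrics.from_counts(pooled)
        roc.append((1.0 - (m.sp or 0.0), m.se or 0.0))
        if m.auc_product > best_auc:
            best_i, best_auc = i, m.auc_product
    return TrainingResult(config=configs[best_i], roc_points=roc, auc_max=best_auc)


@dataclass
class FoldResult:
    held_out: str
    config: ClassifierConfig
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class LeaveOneOutResult:
    folds: list[FoldResult]
    pooled_counts: ConfusionCounts
    pooled: Metrics
    pooled_wheeze: Metrics  # over recordings containing wheeze intervals
    pooled_normal: Metrics


def leave_one_out(
    dataset: list[PreparedRecording],
    base_cfg: ClassifierConfig,
    grid: dict[str, list] | None = None,
    scenario: str = "segment",
    objective: str = "segment",
) -> LeaveOneOutResult:
    """Leave-one-recording-out training and testing.

    Per-recording, per-grid-point confusion counts are computed once and
    reused across folds (each fold's training objective is a pooled sum over
    the other recordings), so the protocol costs one classification pass per
    grid point regardless of the number of folds.
    """
    if len(dataset) < 2:
        raise ValueError("leave-one-out needs at least two recordings")
    grid = grid if grid is not None else default_grid(base_cfg.algorithm)
    configs = _grid_configs(base_cfg, grid)
    train_scorer = score_segmentwise if objective == "segment" else score_phasewise
    test_scorer = score_segmentwise if scenario == "segment" else score_phasewise

    # cache predictions and training-objective counts per (recording, config)
    preds = [[_predict(prep, cfg) for cfg in configs] for prep in dataset]
    train_counts = [
        [train_scorer(preds[i][j], prep.annotation, prep.centers)[0] for j in range(len(configs))]
        for i, prep in enumerate(dataset)
    ]

    folds: list[FoldResult] = []
    pooled = ConfusionCounts()
    pooled_w = ConfusionCounts()
    pooled_n = ConfusionCounts()
    for i, prep in enumerate(dataset):
        best_j, best_auc = 0, -1.0
        for j in range(len(configs)):
            agg = ConfusionCounts()
            for k in range(len(dataset)):
                if k != i:
                    agg = agg + train_counts[k][j]
            auc = Metrics.from_counts(agg).auc_product
            if auc > best_auc:
                best_j, best_auc = j, auc
        counts, metrics = test_scorer(preds[i][best_j], prep.annotation, prep.centers)
        folds.append(
            FoldResult(held_out=prep.id, config=configs[best_j], counts=counts, metrics=metrics)
        )
        pooled = pooled + counts
        if prep.annotation.wheeze_intervals():
            pooled_w = pooled_w + counts
        else:
            pooled_n = pooled_n + counts
    return LeaveOneOutResult(
        folds=folds,
        pooled_counts=pooled,
        pooled=Metrics.from_counts(pooled),
        pooled_wheeze=Metrics.from_counts(pooled_w),
        pooled_normal=Metrics.from_counts(pooled_n),
    )
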