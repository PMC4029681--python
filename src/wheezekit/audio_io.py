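"""Audio and annotation input/output.

Recordings are mono float arrays normalized to peak amplitude 1, resampled to a
common analysis rate (8 kHz by default, which keeps the whole 100-1500 Hz wheeze
band below Nyquist). Analysis operates on fixed-length segments -- 512 samples
(64 ms at 8 kHz) overlapped by 50% -- so that a wheeze lasting a few hundred
milliseconds spans many segments.

Annotations are sidecar TSV files holding two kinds of rows: class intervals
(wheeze ``W`` / normal ``N``) and respiratory-phase intervals
(``insp``/``exp``/``pause``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Recording",
    "Segment",
    "Annotation",
    "AnnotationError",
    "load_recording",
    "frame_segments",
    "read_annotation",
    "write_annotation",
]

DEFAULT_RATE = 8_000
DEFAULT_SEGMENT = 512
DEFAULT_OVERLAP = 0.5

_LABELS = {"W", "N"}
_PHASES = {"insp", "exp", "pause"}


class AnnotationError(ValueError):
    """Malformed annotation file (carries the offending line number)."""


@dataclass
class Recording:
    """A mono recording: samples in [-1, 1] at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: int
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("Recording requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Segment:
    """One fixed-length analysis frame cut from a recording."""

    samples: np.ndarray
    index: int
    start_time: float


@dataclass
class Annotation:
    """Class intervals plus respiratory-phase intervals, in seconds.

    ``intervals`` rows are ``(start, end, label)`` with label ``W`` or ``N``;
    ``phases`` rows are ``(start, end, phase)`` with phase ``insp``, ``exp`` or
    ``pause``. Only ``W`` intervals need to be listed: any time not covered by
    a ``W`` interval is treated as normal by the scoring code.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    phases: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if end <= start:
                raise ValueError(f"interval end {end} <= start {start}")
            if label not in _LABELS:
                raise ValueError(f"bad interval label {label!r}")
        for start, end, phase in self.phases:
            if end <= start:
                raise ValueError(f"phase end {end} <= start {start}")
            if phase not in _PHASES:
                raise ValueError(f"bad phase name {phase!r}")
        self.intervals.sort()
        self.phases.sort()

    def wheeze_intervals(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == "W"]

    def is_wheeze(self, t: float) -> bool:
        """Reference class at time ``t``: inside any W interval?"""
        return any(s <= t < e for s, e in self.wheeze_intervals())


def load_recording(path: str | Path, target_rate: int = DEFAULT_RATE) -> Recording:
    """Load a PCM WAV file, downmix to mono, resample and peak-normalize.

    Stereo input is downmixed by channel mean. Resampling is polyphase
    rational resampling, so the output length is ``round(n * target/source)``
    up to the resampler's edge policy. The absolute peak is scaled to 1.0
    (recording chains differ in gain; detector thresholds are trained on the
    normalized scale).
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"unreadable or empty audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize into a format error
        raise ValueError(f"not a readable WAV file: {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"empty audio stream: {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)

    if rate != target_rate:
        frac = Fraction(target_rate, int(rate))
        data = resample_poly(data, frac.numerator, frac.denominator)
    peak = np.max(np.abs(data))
    if peak > 0:
        data = data / peak
    return Recording(samples=data, sample_rate=target_rate, id=path.stem)


def frame_segments(
    rec: Recording,
    n: int = DEFAULT_SEGMENT,
    overlap: float = DEFAULT_OVERLAP,
) -> list[Segment]:
    """Cut a recording into ``n``-sample segments overlapped by ``overlap``.

    Segment ``m`` starts at sample ``m * hop`` with
    ``hop = round(n * (1 - overlap))``; trailing samples that do not fill a
    whole segment are discarded.
    """
    if n <= 0:
        raise ValueError("segment length must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = round(n * (1 - overlap))
    if hop == 0:
        raise ValueError("overlap too large: hop rounds to zero samples")
    total = rec.samples.size
    if total < n:
        return []
    count = (total - n) // hop + 1
    return [
        Segment(
            samples=rec.samples[m * hop : m * hop + n],
            index=m,
            start_time=m * hop / rec.sample_rate,
        )
        for m in range(count)
    ]


_HEADER = "start_s\tend_s\tkind\tvalue"


def write_annotation(path: str | Path, annot: Annotation) -> None:
    lines = [_HEADER]
    for start, end, label in annot.intervals:
        lines.append(f"{start:.6f}\t{end:.6f}\tlabel\t{label}")
    for start, end, phase in annot.phases:
        lines.append(f"{start:.6f}\t{end:.6f}\tphase\t{phase}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> Annotation:
    """Parse an annotation TSV; raises :class:`AnnotationError` with the line number."""
    text = Path(path).read_text()
    intervals: list[tuple[float, float, str]] = []
    phases: list[tuple[float, float, str]] = []
    lines = text.splitlines()
    if not lines or lines[0].strip() != _HEADER.strip():
        raise AnnotationError(f"{path}:1: missing header line {_HEADER!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise AnnotationError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: bad time value") from exc
        kind, value = parts[2], parts[3]
        if not math.isfinite(start) or not math.isfinite(end) or end <= start:
            raise AnnotationError(f"{path}:{lineno}: end must exceed start")
        if kind == "label":
            if value not in _LABELS:
                raise AnnotationError(f"{path}:{lineno}: bad label {value!r}")
            intervals.append((start, end, value))
        elif kind == "phase":
            if value not in _PHASES:
                raise AnnotationError(f"{path}:{lineno}: bad phase {value!r}")
            phases.append((start, end, value))
        else:
            raise AnnotationError(f"{path}:{lineno}: unknown kind {kind!r}")
    return Annotation(intervals=intervals, phases=phases)
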