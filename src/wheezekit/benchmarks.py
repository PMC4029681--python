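"""Published reference figures for a fixed-point DSP deployment of the four
detectors, used as inputs to the efficiency and bookkeeping computations.

These numbers are measurement inputs, not things this package computes: cycle
counts come from on-chip profiling of a 16-bit DSP running the classifiers at
a 100 MHz clock with 3.2e6 cycles available between successive 50%-overlapped
64 ms segments, and the accuracy percentages were obtained on a 26-recording
clinical/library dataset that is not redistributable. The threshold values
attached to those runs are fixed-point-scaled and must be retrained before use
on the floating-point pipeline in this package.

``DATASET_TABLE`` reproduces the per-recording bookkeeping of that reference
dataset: 13 normal recordings (N01..N13) and 13 recordings containing wheezing
(W01..W13), with per-recording counts of 64 ms segments, inspiratory +
expiratory phases, and annotated wheeze intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CYCLE_BUDGET",
    "REFERENCE_CYCLES",
    "REFERENCE_METRICS_DURATION",
    "REFERENCE_METRICS_EVENT",
    "DATASET_TABLE",
    "DatasetRow",
    "dataset_bookkeeping",
]

#: cycles available between successive segments (100 MHz clock, 32 ms hop)
CYCLE_BUDGET = 3_200_000

#: measured average cycles per segment for each algorithm
REFERENCE_CYCLES = {1: 77_287, 2: 82_888, 3: 98_957, 4: 59_998}

#: overall sensitivity/specificity/accuracy (%) in the duration-tracking scenario
REFERENCE_METRICS_DURATION = {
    1: {"se": 86.30, "sp": 89.50, "ac": 89.01},
    2: {"se": 87.51, "sp": 93.42, "ac": 92.53},
    3: {"se": 80.10, "sp": 70.56, "ac": 71.98},
    4: {"se": 82.54, "sp": 83.64, "ac": 83.79},
}

#: overall sensitivity/specificity/accuracy (%) in the event-detection scenario
REFERENCE_METRICS_EVENT = {
    1: {"se": 98.46, "sp": 81.08, "ac": 86.39},
    2: {"se": 96.92, "sp": 91.21, "ac": 92.96},
    3: {"se": 76.92, "sp": 89.86, "ac": 85.92},
    4: {"se": 87.69, "sp": 73.28, "ac": 76.52},
}


@dataclass(frozen=True)
class DatasetRow:
    label: str
    duration_s: float
    segments: int
    phases: int
    wheeze_intervals: int
    sample_rate_khz: float


DATASET_TABLE = [
    DatasetRow("N01", 12.76, 398, 8, 0, 44.1),
    DatasetRow("N02", 13.48, 421, 8, 0, 44.1),
    DatasetRow("N03", 10.09, 315, 6, 0, 11.025),
    DatasetRow("N04", 6.48, 202, 4, 0, 11.025),
    DatasetRow("N05", 3.12, 97, 2, 0, 11.025),
    DatasetRow("N06", 6.32, 197, 4, 0, 11.025),
    DatasetRow("N07", 5.33, 166, 4, 0, 11.025),
    DatasetRow("N08", 5.34, 167, 4, 0, 11.025),
    DatasetRow("N09", 12.86, 402, 6, 0, 8.0),
    DatasetRow("N10", 10.09, 315, 11, 0, 11.025),
    DatasetRow("N11", 20.00, 625, 10, 0, 8.0),
    DatasetRow("N12", 9.99, 312, 4, 0, 11.025),
    DatasetRow("N13", 25.76, 805, 11, 0, 44.1),
    DatasetRow("W01", 11.89, 371, 11, 7, 44.1),
    DatasetRow("W02", 26.73, 835, 10, 5, 22.05),
    DatasetRow("W03", 15.83, 494, 16, 7, 22.05),
    DatasetRow("W04", 4.60, 143, 4, 3, 11.025),
    DatasetRow("W05", 8.04, 251, 7, 3, 11.025),
    DatasetRow("W06", 10.10, 315, 9, 4, 11.025),
    DatasetRow("W07", 20.00, 625, 12, 6, 8.0),
    DatasetRow("W08", 7.52, 235, 6, 3, 11.025),
    DatasetRow("W09", 9.48, 296, 6, 3, 44.1),
    DatasetRow("W10", 10.15, 317, 8, 4, 8.0),
    DatasetRow("W11", 29.96, 936, 30, 15, 44.1),
    DatasetRow("W12", 10.60, 331, 6, 2, 8.0),
    DatasetRow("W13", 9.70, 303, 6, 3, 8.0),
]

#: number of respiratory phases annotated positive (containing wheezing)
REFERENCE_POSITIVE_PHASES = 65


def dataset_bookkeeping() -> dict[str, int]:
    """Derived sample counts of the reference dataset.

    Segment-wise scoring uses every 64 ms segment as a sample; phase-wise
    scoring uses every inspiratory/expiratory phase, with the positives being
    the phases containing wheezing and every remaining phase a negative.
    """
    normal = [r for r in DATASET_TABLE if r.label.startswith("N")]
    wheeze = [r for r in DATASET_TABLE if r.label.startswith("W")]
    seg_normal = sum(r.segments for r in normal)
    seg_wheeze = sum(r.segments for r in wheeze)
    phases_normal = sum(r.phases for r in normal)
    phases_wheeze = sum(r.phases for r in wheeze)
    positives = REFERENCE_POSITIVE_PHASES
    return {
        "recordings": len(DATASET_TABLE),
        "segments_normal": seg_normal,
        "segments_wheeze": seg_wheeze,
        "segments_total": seg_normal + seg_wheeze,
        "phases_normal_recordings": phases_normal,
        "phases_wheeze_recordings": phases_wheeze,
        "phases_total": phases_normal + phases_wheeze,
        "positive_phases": positives,
        "negative_phases": phases_normal + phases_wheeze - positives,
        "wheeze_intervals": sum(r.wheeze_intervals for r in wheeze),
    }
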