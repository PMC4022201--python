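"""Evaluation formulas: precision of sampled associations, speedup, sizeup.

Precision scores a manually curated sample of derived associations.
Speedup and sizeup are the standard scalability ratios for a distributed
run: time on the baseline configuration over time on the scaled-up cluster,
and time for m-fold data over time for the base data, respectively. The
baseline is whatever configuration the evaluation designates — not
necessarily one machine, since the smallest configuration able to hold the
data may already be a small cluster.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EvaluationCounts:
    """True / false positive counts from a manual evaluation sample."""

    tp: int
    fp: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("tp and fp must be non-negative")

    @classmethod
    def from_sample(cls, sample_size: int, tp: int) -> "EvaluationCounts":
        if tp > sample_size:
            raise ValueError(f"tp={tp} exceeds sample size {sample_size}")
        return cls(tp=tp, fp=sample_size - tp)


@dataclass(frozen=True)
class TimingPair:
    """Baseline and measured wall-clock times, in minutes."""

    baseline_minutes: float
    measured_minutes: float

    def __post_init__(self) -> None:
        if self.baseline_minutes <= 0 or self.measured_minutes <= 0:
            raise ValueError("times must be strictly positive")


def precision(counts: EvaluationCounts) -> float:
    """TP / (TP + FP); undefined (raises) on an empty sample."""
    total = counts.tp + counts.fp
    if total == 0:
        raise ValueError("precision undefined: tp + fp == 0")
    return counts.tp / total


def speedup(t: TimingPair) -> float:
    """Baseline time over measured time; > 1 means the cluster is faster."""
    return t.baseline_minutes / t.measured_minutes


def sizeup(t: TimingPair) -> float:
    """Measured time (m-fold data) over baseline time; <= m indicates sublinear growth."""
    return t.measured_minutes / t.baseline_minutes
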