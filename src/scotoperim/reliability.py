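"""Exam reliability: fixation stability, catch-trial losses, rod-free
zone detection, and the exclusion gate.

Fixation losses are presses in response to suprathreshold stimuli
presented to the physiological blind spot — false positives.  Under
dark-adapted cyan testing the rod-free fovea should be a scotoma, so a
high central cyan threshold is a second proxy for unreliable
responding; exams failing either check are gated out of analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .exam import Color, Condition, Exam, NON_SEEN

#: Exams with a fixation-loss percentage at or above this fail the gate.
DEFAULT_FL_CUTOFF_PCT = 30.0
#: Central cyan thresholds above this indicate absent rod-free mapping.
DEFAULT_ROD_FREE_CUTOFF_DB = 8.0

# chi-square quantile scalings k = -ln(1-P) for the contour ellipse;
# the "63%" output uses the exact 1 - 1/e convention (k = 1).
BCEA_COVERAGE_K = {0.63: 1.0, 0.95: -math.log(0.05)}


class FujiiClass(str, Enum):
    STABLE = "stable"
    RELATIVELY_UNSTABLE = "relatively_unstable"
    UNSTABLE = "unstable"


class ExclusionReason(str, Enum):
    HIGH_FIXATION_LOSSES = "high_fixation_losses"
    ROD_FREE_ABSENT = "rod_free_absent"


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class FixationMetrics:
    P1: float  # % of fixation samples within 1 degree of the PRL
    P2: float  # % within 2 degrees
    BCEA63: float  # deg^2
    BCEA95: float  # deg^2
    fujii_class: FujiiClass

    def __post_init__(self) -> None:
        if not (0.0 <= self.P1 <= self.P2 <= 100.0):
            raise ValueError("need 0 <= P1 <= P2 <= 100")
        if self.BCEA63 < 0 or self.BCEA95 < self.BCEA63:
            raise ValueError("need 0 <= BCEA63 <= BCEA95")


@dataclass(frozen=True)
class ReliabilityReport:
    subject_id: str
    fixation_loss_pct: float
    metrics: FixationMetrics
    rod_free_detected: bool | None  # None where not applicable (non-cyan)
    passed: bool
    reasons: tuple[ExclusionReason, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")


def fixation_loss_rate(catch_trials: Sequence[bool]) -> float:
    """Percentage of blind-spot catch trials with a press (false positives)."""
    if len(catch_trials) == 0:
        raise InsufficientDataError("fixation-loss rate undefined with zero catch trials")
    return 100.0 * sum(bool(p) for p in catch_trials) / len(catch_trials)


def preferred_retinal_locus(trace: np.ndarray) -> np.ndarray:
    """PRL estimate: coordinate-wise median of the fixation trace.

    The median is robust to saccadic outliers; the device's own
    estimator is unpublished, so this choice is configurable by passing
    an explicit center to :func:`p1_p2`.
    """
    return np.median(trace, axis=0)


def p1_p2(fixation_trace, center: np.ndarray | None = None) -> tuple[float, float]:
    """Percentages of fixation samples within 1 and 2 degrees of the PRL."""
    trace = np.asarray(fixation_trace, dtype=float).reshape(-1, 2)
    if len(trace) == 0:
        raise InsufficientDataError("empty fixation trace")
    if center is None:
        center = preferred_retinal_locus(trace)
    r = np.hypot(*(trace - center).T)
    return (100.0 * float(np.mean(r <= 1.0)), 100.0 * float(np.mean(r <= 2.0)))


def classify_fujii(P1: float, P2: float) -> FujiiClass:
    """Fixation stability classification from P1/P2.

    Stable: P1 > 75%.  Relatively unstable: P1 <= 75% but P2 > 75%.
    Unstable: P2 <= 75%.  Boundary cases follow the strict inequalities
    of the original definition.
    """
    if P1 > 75.0:
        return FujiiClass.STABLE
    if P2 > 75.0:
        return FujiiClass.RELATIVELY_UNSTABLE
    return FujiiClass.UNSTABLE


def bcea(fixation_trace, coverage: float = 0.63) -> float:
    """Bivariate contour ellipse area (deg^2) at a coverage proportion.

    BCEA(P) = 2 k pi sigma_x sigma_y sqrt(1 - rho^2), with
    k = -ln(1 - P) (k = 1 for the 63.2% contour, k ~ 2.996 for 95%) and
    sample SDs / correlation of the trace.  A zero-variance trace has
    zero area; fewer than 3 samples is an error.
    """
    trace = np.asarray(fixation_trace, dtype=float).reshape(-1, 2)
    if len(trace) < 3:
        raise InsufficientDataError("BCEA requires at least 3 fixation samples")
    k = BCEA_COVERAGE_K.get(round(coverage, 2), -math.log1p(-coverage))
    sx = trace[:, 0].std(ddof=1)
    sy = trace[:, 1].std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    rho = float(np.corrcoef(trace[:, 0], trace[:, 1])[0, 1])
    rho2 = min(rho * rho, 1.0)
    return float(2.0 * k * math.pi * sx * sy * math.sqrt(1.0 - rho2))


def fixation_metrics(fixation_trace) -> FixationMetrics:
    p1, p2 = p1_p2(fixation_trace)
    return FixationMetrics(p1, p2, bcea(fixation_trace, 0.63),
                           bcea(fixation_trace, 0.95), classify_fujii(p1, p2))


def detect_rod_free_zone(cyan_exam: Exam,
                         cutoff: float = DEFAULT_ROD_FREE_CUTOFF_DB) -> bool:
    """Whether the central cyan locus shows the expected rod-free scotoma.

    Detected iff the central-locus threshold is at or below ``cutoff``
    (the non-seen sentinel counts as detected — a full central scotoma
    is the expected physiology).
    """
    if cyan_exam.color is not Color.CYAN or cyan_exam.condition is not Condition.SCOTOPIC:
        raise ValueError("rod-free detection applies to scotopic cyan exams")
    idx = cyan_exam.grid.central_index()
    if idx is None:
        raise ValueError("grid has no central (0,0) locus; rod-free check not applicable")
    central = cyan_exam.thresholds[idx]
    return central == NON_SEEN or central <= cutoff


def gate_exam(exam: Exam,
              fl_cutoff: float = DEFAULT_FL_CUTOFF_PCT,
              rodfree_cutoff: float = DEFAULT_ROD_FREE_CUTOFF_DB) -> ReliabilityReport:
    """Apply the reliability exclusion gate to one exam.

    Fails with ``high_fixation_losses`` when the fixation-loss
    percentage is at or above ``fl_cutoff`` (default 30%), and with
    ``rod_free_absent`` when a scotopic cyan exam lacks the central
    scotoma.  All reasons are reported, not just the first.
    """
    fl = fixation_loss_rate(exam.catch_trials)
    metrics = fixation_metrics(exam.fixation_trace)
    reasons: list[ExclusionReason] = []
    if fl >= fl_cutoff:
        reasons.append(ExclusionReason.HIGH_FIXATION_LOSSES)
    rod_free: bool | None = None
    if exam.color is Color.CYAN and exam.condition is Condition.SCOTOPIC:
        rod_free = detect_rod_free_zone(exam, rodfree_cutoff)
        if not rod_free:
            reasons.append(ExclusionReason.ROD_FREE_ABSENT)
    return ReliabilityReport(
        subject_id=exam.subject_id, fixation_loss_pct=fl, metrics=metrics,
        rod_free_detected=rod_free, passed=not reasons, reasons=tuple(reasons),
    )


def gate_exams(exams: Iterable[Exam], **kwargs) -> list[ReliabilityReport]:
    """Gate a collection of exams; deterministic and order-independent
    per exam."""
    return [gate_exam(e, **kwargs) for e in exams]
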