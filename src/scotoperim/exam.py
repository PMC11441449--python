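"""Exam and subject domain types.

An :class:`Exam` is one stimulus-color microperimetry test: a threshold
sensitivity (dB of stimulus attenuation; higher = better) at every grid
locus, plus the fixation trace, blind-spot catch trials and metadata
needed for reliability assessment.  Loci where the brightest stimulus
(0 dB attenuation) was not detected carry the non-seen sentinel −1.0 dB,
stored verbatim; all downstream index code branches on it explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .grid import Grid

#: Export sentinel for loci where the brightest stimulus was not seen.
NON_SEEN = -1.0

#: Device dynamic range in dB of attenuation.
DB_MIN = 0.0
DB_MAX = 36.0

#: Emmetropic retinal scale: 1 degree of visual angle ~ 0.288 mm on the
#: retina.  The single place where degrees and millimetres meet.
MM_PER_DEG = 0.288


def dynamic_range_db(max_luminance: float, min_luminance: float) -> float:
    """Dynamic range in dB between the brightest and dimmest stimulus.

    A 1.0 dB sensitivity step is a 0.1 log-unit luminance step, so the
    range spanned by luminances L_max..L_min is 10*log10(L_max/L_min).
    """
    if min_luminance <= 0 or max_luminance <= 0:
        raise ValueError("luminances must be positive")
    return 10.0 * math.log10(max_luminance / min_luminance)


class Eye(str, Enum):
    OD = "OD"
    OS = "OS"


class Condition(str, Enum):
    SCOTOPIC = "scotopic"
    MESOPIC = "mesopic"


class Color(str, Enum):
    CYAN = "cyan_505nm"
    RED = "red_627nm"
    WHITE = "white"


class Session(str, Enum):
    TEST1 = "test1"
    TEST2 = "test2"


class Group(str, Enum):
    HEALTHY = "healthy"
    CHOROIDEREMIA = "choroideremia"


def _valid_threshold(t: float) -> bool:
    return t == NON_SEEN or (DB_MIN <= t <= DB_MAX)


@dataclass(frozen=True)
class Exam:
    subject_id: str
    eye: Eye
    condition: Condition
    color: Color
    grid: Grid
    thresholds: tuple[float, ...]  # per-locus dB, NON_SEEN sentinel allowed
    fixation_trace: tuple[tuple[float, float], ...] = ()
    catch_trials: tuple[bool, ...] = ()  # True = pressed (false positive)
    fixation_target_intensity: float = 5.0  # log units
    duration_s: float = float("nan")
    session: Session = Session.TEST1
    eye_normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.grid):
            raise ValueError(
                f"{len(self.thresholds)} thresholds for a {len(self.grid)}-locus grid"
            )
        for i, t in enumerate(self.thresholds):
            if not _valid_threshold(t):
                raise ValueError(
                    f"threshold {t} at locus index {i} outside {{-1.0}} U [0, 36]"
                )

    @property
    def threshold_array(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=float)

    @property
    def trace_array(self) -> np.ndarray:
        return np.asarray(self.fixation_trace, dtype=float).reshape(-1, 2)

    def n_non_seen(self) -> int:
        """Number of loci at the non-seen sentinel (floor effect)."""
        return int(np.sum(self.threshold_array == NON_SEEN))

    def key(self) -> tuple[Condition, Color, Session]:
        return (self.condition, self.color, self.session)


def normalize_eye(exam: Exam) -> Exam:
    """Mirror a left-eye (OS) exam into the right-eye (OD) convention.

    OS loci and fixation samples are reflected x -> −x so that +x is the
    temporal retina for every exam, making hemifield pooling a sign test
    on x.  OD exams and already-normalized exams pass through unchanged,
    so the operation is idempotent after its first application.
    """
    if exam.eye is Eye.OD or exam.eye_normalized:
        return exam
    mirrored_grid = Grid(
        tuple(replace(l, x=-l.x if l.x != 0.0 else 0.0) for l in exam.grid.loci),
        exam.grid.kind,
        exam.grid.ring_radii,
        exam.grid.points_per_ring,
    )
    trace = tuple((-x if x != 0.0 else 0.0, y) for x, y in exam.fixation_trace)
    return replace(exam, grid=mirrored_grid, fixation_trace=trace, eye_normalized=True)


@dataclass
class SubjectRecord:
    """One participant: group label, optional structural marker, exams."""

    subject_id: str
    group: Group
    island_area_mm2: float | None = None  # residual autofluorescent island
    exams: dict[tuple[Condition, Color, Session], Exam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.island_area_mm2 is not None and not self.island_area_mm2 > 0:
            raise ValueError("island_area_mm2 must be > 0 when present")

    def add(self, exam: Exam) -> None:
        if exam.subject_id != self.subject_id:
            raise ValueError("exam subject_id mismatch")
        self.exams[exam.key()] = exam

    def get(self, condition: Condition | str, color: Color | str,
            session: Session | str = Session.TEST1) -> Exam | None:
        return self.exams.get((Condition(condition), Color(color), Session(session)))
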