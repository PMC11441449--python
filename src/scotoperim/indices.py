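"""Pointwise, mean and volumetric sensitivity indices and cyan-red
difference maps.

Mean sensitivity (MS) averages the pointwise thresholds, mapping the
−1.0 non-seen sentinel to 0.0 dB (the device reports 0.0-dB means for
fully non-seeing exams even though pointwise exports carry −1.0).  On a
radial grid MS is spatially weighted toward the denser center; volume
sensitivity (VS) — the integral of the piecewise-linear hill-of-vision
surface over the grid footprint, in dB·deg² — is immune to that
sampling-density bias and to floor-averaging effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .exam import Color, Exam, NON_SEEN, DB_MAX
from .exam import normalize_eye as _normalize_eye

#: The device's default pointwise cyan-red difference display limit.
DEVICE_DIFFERENCE_LIMIT_DB = 4.0
#: Combined test-retest variability limit for the remodeled plot.
TRTV_DIFFERENCE_LIMIT_DB = 13.0


class DifferenceClass(str, Enum):
    EQUAL_NORMAL = "equal_normal"  # gray: normal dark-adapted function
    EQUAL_REDUCED = "equal_reduced"  # black: equally impaired rods and cones
    ROD_DYSFUNCTION = "rod_dysfunction"  # red: cyan reduced relative to red
    CONE_DYSFUNCTION = "cone_dysfunction"  # blue: red reduced relative to cyan


@dataclass(frozen=True)
class SensitivityIndices:
    pointwise: tuple[float, ...]  # raw thresholds, sentinel preserved
    mean_sensitivity: float  # dB
    volume_sensitivity: float  # dB deg^2
    temporal_mean: float  # dB
    nasal_mean: float  # dB
    central_excluded: bool


@dataclass(frozen=True)
class DifferenceMap:
    locus_ids: tuple[int, ...]
    cyan_minus_red: tuple[float, ...]  # nan where undefined
    classes: tuple[DifferenceClass | None, ...] | None
    threshold_used: float | None


def _filled(exam: Exam) -> np.ndarray:
    """Thresholds with the non-seen sentinel mapped to 0.0 dB."""
    t = exam.threshold_array.copy()
    t[t == NON_SEEN] = 0.0
    return t


def mean_sensitivity(exam: Exam, central_excluded: bool = False) -> float:
    """Arithmetic mean of pointwise sensitivities, in dB.

    Non-seen loci contribute 0.0 dB.  ``central_excluded`` drops the
    (0,0) locus, removing the rod-free-fovea bias from cyan means.
    """
    values = _filled(exam)
    if central_excluded:
        idx = exam.grid.central_index()
        if idx is not None:
            values = np.delete(values, idx)
    if values.size == 0:
        raise ValueError("no loci to average")
    return float(values.mean())


def volume_sensitivity(exam: Exam) -> float:
    """Hill-of-vision volume in dB·deg².

    Integrates the piecewise-linear interpolant of the (sentinel->0)
    pointwise surface over the Delaunay triangulation of the loci —
    exactly: each triangle contributes area x mean of its vertex
    values.  No extrapolation beyond the convex hull.
    """
    xy = exam.grid.xy
    values = _filled(exam)
    try:
        tri = Delaunay(xy)
    except QhullError as err:
        raise ValueError("degenerate grid geometry for volume integration") from err
    simplices = tri.simplices
    p = xy[simplices]  # (m, 3, 2)
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    return float(np.sum(areas * values[simplices].mean(axis=1)))


def hemifield_means(exam: Exam) -> tuple[float, float]:
    """(temporal_mean, nasal_mean) in dB, sentinel -> 0.

    The exam is eye-normalized first, so temporal is x > 0 for either
    eye; loci on the vertical meridian (x = 0) belong to neither
    hemifield.
    """
    exam = _normalize_eye(exam)
    x = exam.grid.xy[:, 0]
    values = _filled(exam)
    temporal = values[x > 0]
    nasal = values[x < 0]
    t = float(temporal.mean()) if temporal.size else 0.0
    n = float(nasal.mean()) if nasal.size else 0.0
    return t, n


def compute_indices(exam: Exam, central_excluded: bool = False) -> SensitivityIndices:
    temporal, nasal = hemifield_means(exam)
    return SensitivityIndices(
        pointwise=exam.thresholds,
        mean_sensitivity=mean_sensitivity(exam, central_excluded),
        volume_sensitivity=volume_sensitivity(exam),
        temporal_mean=temporal,
        nasal_mean=nasal,
        central_excluded=central_excluded,
    )


def pointwise_difference(cyan_exam: Exam, red_exam: Exam) -> DifferenceMap:
    """Per-locus cyan − red difference map (dB).

    Undefined (NaN) where either threshold is the non-seen sentinel;
    such loci are handled by :func:`classify_difference` under the
    both-non-seen policy.  Requires identical grids within one subject
    and session.
    """
    if cyan_exam.grid.loci != red_exam.grid.loci:
        raise ValueError("cyan and red exams must share a grid")
    if cyan_exam.color is not Color.CYAN or red_exam.color is not Color.RED:
        raise ValueError("expected a (cyan, red) exam pair")
    c = cyan_exam.threshold_array
    r = red_exam.threshold_array
    diff = c - r
    diff[(c == NON_SEEN) | (r == NON_SEEN)] = np.nan
    return DifferenceMap(tuple(cyan_exam.grid.locus_ids), tuple(diff), None, None)


def classify_difference(
    cyan_exam: Exam,
    red_exam: Exam,
    threshold: float = DEVICE_DIFFERENCE_LIMIT_DB,
    normative_pointwise: np.ndarray | None = None,
    both_non_seen_reduced: bool = True,
) -> DifferenceMap:
    """Classify each locus of a cyan-red difference map.

    |diff| <= threshold -> an "equal" class: ``equal_normal`` when both
    thresholds are within normative bounds, else ``equal_reduced``;
    diff < −threshold -> ``rod_dysfunction``; diff > +threshold ->
    ``cone_dysfunction``.  Thresholds of 0, 4 and 13 dB correspond to
    the raw, device-default and test-retest-variability-adjusted plots.

    ``normative_pointwise`` is the per-locus lower normative bound
    (e.g. healthy mean − 2 SD); with none supplied every seen locus
    counts as within bounds.  Loci non-seen in both colors default to
    ``equal_reduced``; loci non-seen in exactly one color are
    unclassified (None).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    base = pointwise_difference(cyan_exam, red_exam)
    c = cyan_exam.threshold_array
    r = red_exam.threshold_array
    if normative_pointwise is None:
        lower = np.full(len(c), -np.inf)
    else:
        lower = np.asarray(normative_pointwise, dtype=float)
    classes: list[DifferenceClass | None] = []
    for i, d in enumerate(base.cyan_minus_red):
        if np.isnan(d):
            both = c[i] == NON_SEEN and r[i] == NON_SEEN
            classes.append(DifferenceClass.EQUAL_REDUCED
                           if both and both_non_seen_reduced else None)
        elif d < -threshold:
            classes.append(DifferenceClass.ROD_DYSFUNCTION)
        elif d > threshold:
            classes.append(DifferenceClass.CONE_DYSFUNCTION)
        else:
            reduced = c[i] < lower[i] or r[i] < lower[i]
            classes.append(DifferenceClass.EQUAL_REDUCED if reduced
                           else DifferenceClass.EQUAL_NORMAL)
    return DifferenceMap(base.locus_ids, base.cyan_minus_red,
                         tuple(classes), float(threshold))


def normative_lower_bounds(healthy_exams: list[Exam], n_sd: float = 2.0) -> np.ndarray:
    """Per-locus lower normative bound from a healthy reference cohort.

    mean − ``n_sd`` x SD of the (sentinel->0) pointwise values, locus
    by locus, over the supplied exams (all on one grid).
    """
    if not healthy_exams:
        raise ValueError("need at least one reference exam")
    stack = np.vstack([_filled(e) for e in healthy_exams])
    return stack.mean(axis=0) - n_sd * stack.std(axis=0, ddof=1 if len(stack) > 1 else 0)


def summary_difference_indices(
    cyan_exam: Exam, red_exam: Exam, central_excluded: bool = False
) -> tuple[float, float]:
    """(mean-sensitivity difference dB, volume difference dB·deg²),
    cyan minus red, optionally recomputed without the central locus."""
    ms = mean_sensitivity(cyan_exam, central_excluded) \
        - mean_sensitivity(red_exam, central_excluded)
    vs = volume_sensitivity(cyan_exam) - volume_sensitivity(red_exam)
    return ms, vs
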