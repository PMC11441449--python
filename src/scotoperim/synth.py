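"""Synthetic scotopic microperimetry cohorts.

Generates exams with the statistical structure the downstream analysis
assumes, so every stage is testable without patient data:

* a psychometric observer (cumulative-Gaussian detection in dB with
  false-positive and lapse mixture) driving a 4-2 dB bracketing
  staircase at each locus;
* parametric "true" sensitivity fields — a healthy hill of vision with
  a rod-free foveal cyan scotoma, or a choroideremia-like residual
  central island with temporal sparing, color-specific deficits and a
  non-seen floor outside the island;
* bivariate-normal fixation jitter and Bernoulli catch-trial presses;
* a test2 session re-run on the same true field with independent
  observer noise plus an additive within-subject perturbation, so the
  staircase and biological variance components stay separable.

Cyan and red share one dB scale: the device's ~20 dB radiance offset
between colors is treated as absorbed into the per-color calibration
(per the CIE scotopic luminosity calibration), so equal deficits give a
0.0 dB cyan-minus-red difference away from the fovea.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.special import ndtr

from .exam import (
    Color, Condition, DB_MAX, DB_MIN, Exam, Eye, Group, MM_PER_DEG, NON_SEEN,
    Session, SubjectRecord,
)
from .grid import Grid, build_grid

STAIRCASE_START_DB = 18.0
STAIRCASE_COARSE_STEP = 4.0
STAIRCASE_FINE_STEP = 2.0
STAIRCASE_MAX_PRESENTATIONS = 100


@dataclass(frozen=True)
class ObserverModel:
    """Psychometric observer for staircase simulation.

    Probability of reporting a presentation at attenuation level L when
    the true threshold is T:

        p(seen) = fp + (1 - fp - lapse) * Phi((T - L) / slope)

    ``slope=0`` gives the deterministic step observer (seen iff L <= T).
    For a non-seen true threshold the detection term is zero and only
    false positives can produce a press.
    """

    psychometric_slope: float = 1.5  # dB
    false_positive_rate: float = 0.03
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.psychometric_slope < 0:
            raise ValueError("psychometric_slope must be >= 0")
        for r in (self.false_positive_rate, self.lapse_rate):
            if not 0.0 <= r <= 0.5:
                raise ValueError("rates must lie in [0, 0.5]")

    def p_seen(self, level: float, true_threshold: float) -> float:
        if true_threshold == NON_SEEN:
            p_detect = 0.0
        elif self.psychometric_slope == 0.0:
            p_detect = 1.0 if level <= true_threshold else 0.0
        else:
            p_detect = float(ndtr((true_threshold - level) / self.psychometric_slope))
        return (self.false_positive_rate
                + (1.0 - self.false_positive_rate - self.lapse_rate) * p_detect)


DETERMINISTIC_OBSERVER = ObserverModel(0.0, 0.0, 0.0)


def run_staircase(
    true_threshold: float,
    observer: ObserverModel = DETERMINISTIC_OBSERVER,
    rng: np.random.Generator | None = None,
    start: float = STAIRCASE_START_DB,
) -> float:
    """Simulate one 4-2 dB bracketing threshold staircase.

    Levels step 4 dB brighter after each not-seen response (4 dB dimmer
    after seen); the first not-seen-to-seen reversal switches to 2 dB
    steps, and the staircase terminates at the second such reversal,
    returning the last seen level.  If the brightest stimulus (0 dB) is
    never seen the non-seen sentinel −1.0 is returned; a seen response
    at the dimmest stimulus (36 dB) terminates at the ceiling.
    """
    if rng is None:
        rng = np.random.default_rng()
    level = float(np.clip(start, DB_MIN, DB_MAX))
    step = STAIRCASE_COARSE_STEP
    reversals = 0
    last_seen: float | None = None
    prev_seen: bool | None = None
    for _ in range(STAIRCASE_MAX_PRESENTATIONS):
        seen = rng.random() < observer.p_seen(level, true_threshold)
        if seen:
            last_seen = level
            if prev_seen is False:
                reversals += 1
                step = STAIRCASE_FINE_STEP
                if reversals >= 2:
                    return level
            if level >= DB_MAX:
                return DB_MAX
            level = min(level + step, DB_MAX)
        else:
            if level <= DB_MIN:
                return NON_SEEN if last_seen is None else last_seen
            level = max(level - step, DB_MIN)
        prev_seen = seen
    return NON_SEEN if last_seen is None else last_seen


# ---------------------------------------------------------------------------
# True sensitivity fields


@dataclass(frozen=True)
class SensitivityField:
    """Parametric ground-truth sensitivity surface for one subject.

    Healthy: a radially declining hill of vision, ``peak - slope * r``
    clamped to the 0–36 dB range, with cyan inside the rod-free radius
    replaced by a low foveal residual (cone response to bright cyan).
    Choroideremia: the healthy surface minus a color-specific deficit
    inside a residual elliptical island centered temporally; non-seen
    outside the island or where the deficit exhausts the sensitivity.
    """

    profile: Group = Group.HEALTHY
    peak_cyan: float = 22.0  # dB
    peak_red: float = 22.0  # dB
    radial_slope: float = 0.4  # dB per degree
    rod_free_radius: float = 0.5  # degrees
    central_cyan_residual: float = 4.0  # dB
    island_semi_axes: tuple[float, float] | None = None  # degrees (a, b)
    island_center_offset: float = 1.5  # degrees, temporal (+x) shift
    cyan_deficit: float = 0.0  # dB
    red_deficit: float = 0.0  # dB

    def __post_init__(self) -> None:
        if self.rod_free_radius < 0:
            raise ValueError("rod_free_radius must be >= 0")
        if self.cyan_deficit < 0 or self.red_deficit < 0:
            raise ValueError("deficits must be >= 0")
        if self.profile is Group.CHOROIDEREMIA:
            if self.island_semi_axes is None or min(self.island_semi_axes) <= 0:
                raise ValueError("choroideremia field requires positive island axes")

    def island_area_mm2(self) -> float | None:
        """Residual island area in mm^2 (ellipse area, deg->mm scaled)."""
        if self.island_semi_axes is None:
            return None
        a, b = self.island_semi_axes
        return math.pi * a * b * MM_PER_DEG**2


def true_threshold(field: SensitivityField, color: Color | str,
                   x: float, y: float) -> float:
    """Ground-truth threshold (dB) of a field at a locus, or −1.0 non-seen."""
    color = Color(color)
    r = math.hypot(x, y)
    peak = field.peak_cyan if color is Color.CYAN else field.peak_red
    value = float(np.clip(peak - field.radial_slope * r, DB_MIN, DB_MAX))
    foveal_cyan = color is Color.CYAN and r <= field.rod_free_radius
    if foveal_cyan:
        value = field.central_cyan_residual
    if field.profile is Group.CHOROIDEREMIA:
        a, b = field.island_semi_axes
        inside = ((x - field.island_center_offset) / a) ** 2 + (y / b) ** 2 <= 1.0
        if not inside:
            return NON_SEEN
        if not foveal_cyan:  # foveal cone response to bright cyan is spared
            value -= field.cyan_deficit if color is Color.CYAN else field.red_deficit
        if value < DB_MIN:
            return NON_SEEN
    return float(np.clip(value, DB_MIN, DB_MAX))


# ---------------------------------------------------------------------------
# Exam and cohort simulation


@dataclass(frozen=True)
class FixationModel:
    """Bivariate-normal fixation jitter around the preferred locus."""

    sigma_x: float = 0.25  # degrees
    sigma_y: float = 0.25
    rho: float = 0.0
    n_samples: int = 300

    def sample(self, rng: np.random.Generator) -> tuple[tuple[float, float], ...]:
        cov = np.array([
            [self.sigma_x**2, self.rho * self.sigma_x * self.sigma_y],
            [self.rho * self.sigma_x * self.sigma_y, self.sigma_y**2],
        ])
        pts = rng.multivariate_normal([0.0, 0.0], cov, size=self.n_samples,
                                      method="svd")
        return tuple((float(x), float(y)) for x, y in pts)


def simulate_exam(
    field: SensitivityField,
    grid: Grid,
    observer: ObserverModel,
    rng: np.random.Generator,
    color: Color | str = Color.CYAN,
    fixation: FixationModel = FixationModel(),
    n_catch_trials: int = 10,
    subject_id: str = "S00",
    eye: Eye = Eye.OD,
    session: Session = Session.TEST1,
    condition: Condition = Condition.SCOTOPIC,
    threshold_offset: np.ndarray | None = None,
) -> Exam:
    """Simulate one exam: a staircase at every locus plus fixation and
    catch-trial streams.

    ``threshold_offset`` is an optional per-locus additive perturbation
    of the true field (used for retest biological noise).
    """
    color = Color(color)
    thresholds = []
    n_presentations = 0
    # the field lives in retinal coordinates with +x temporal (OD frame);
    # an OS exam's stored +x axis is the nasal retina, so evaluate the
    # field at the mirrored abscissa — eye normalization then recovers
    # the true temporal/nasal pattern
    mirror = -1.0 if eye is Eye.OS else 1.0
    for i, locus in enumerate(grid.loci):
        t = true_threshold(field, color, mirror * locus.x, locus.y)
        if threshold_offset is not None and t != NON_SEEN:
            t = float(np.clip(t + threshold_offset[i], DB_MIN, DB_MAX))
        thresholds.append(run_staircase(t, observer, rng))
        n_presentations += 6  # bookkeeping only, for a plausible duration
    trace = fixation.sample(rng)
    catch = tuple(bool(p) for p in
                  rng.random(n_catch_trials) < observer.false_positive_rate)
    duration = 60.0 * (4.0 + rng.random() * 2.5)
    return Exam(
        subject_id=subject_id, eye=eye, condition=condition, color=color,
        grid=grid, thresholds=tuple(thresholds), fixation_trace=trace,
        catch_trials=catch,
        fixation_target_intensity=5.0 if field.profile is Group.HEALTHY
        else float(20 + rng.integers(0, 60)),
        duration_s=duration, session=session,
    )


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters for cohort simulation.

    Defaults emulate the published study's setting: groups of healthy
    controls and choroideremia patients on the 37-locus scotopic radial
    grid, cyan and red exams, and a same-day retest session.
    """

    n_per_group: int = 16
    grid: Grid | None = None
    observer: ObserverModel = ObserverModel()
    retest_sd_within: float = 1.5  # dB, biological/criterion drift
    n_catch_trials: int = 10
    seed: int = 0
    # healthy field priors (mean, sd); the peak prior sits ~1.3 dB above
    # the target true surface because the staircase's last-seen estimator
    # reads low by about that much, so *measured* healthy indices land on
    # a realistic scale (mean sensitivity ~20.6 dB)
    peak_mean: float = 23.3
    peak_sd: float = 0.8
    slope_mean: float = 0.4
    slope_sd: float = 0.05
    rod_free_radius: float = 0.5
    central_residual_mean: float = 4.0
    central_residual_sd: float = 2.0
    # choroideremia priors
    chm_central_residual_mean: float = 1.0
    chm_island_a_max: float = 8.0
    chm_island_a_min: float = 1.2
    chm_island_aspect: float = 0.75
    chm_island_offset: float = 1.5
    chm_cyan_deficit_base: float = 14.0
    chm_cyan_deficit_span: float = 8.0
    chm_red_deficit_base: float = 4.0
    chm_red_deficit_span: float = 10.0
    # fixation priors
    fixation_sigma_mean: float = 0.25
    fixation_sigma_sd: float = 0.08
    fixation_rho: float = 0.0
    fixation_n_samples: int = 300
    os_fraction: float = 0.3
    with_retest: bool = True
    colors: tuple[Color, ...] = (Color.CYAN, Color.RED)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.retest_sd_within < 0:
            raise ValueError("retest_sd_within must be >= 0")
        if self.grid is None:
            self.grid = build_grid()


def draw_field(config: SyntheticCohortConfig, group: Group,
               rng: np.random.Generator) -> SensitivityField:
    """Draw one subject's true sensitivity field from the cohort priors."""
    peak = rng.normal(config.peak_mean, config.peak_sd)
    slope = max(0.0, rng.normal(config.slope_mean, config.slope_sd))
    if group is Group.HEALTHY:
        residual = float(np.clip(
            rng.normal(config.central_residual_mean, config.central_residual_sd),
            DB_MIN, 10.0))
        return SensitivityField(
            profile=Group.HEALTHY, peak_cyan=peak, peak_red=peak,
            radial_slope=slope, rod_free_radius=config.rod_free_radius,
            central_cyan_residual=residual)
    # disease severity in (0, 1]: island shrinks and the cone (red)
    # deficit grows with severity; the rod (cyan) deficit is large
    # throughout, emulating early rod loss with later cone involvement
    severity = rng.uniform(0.15, 1.0)
    a = config.chm_island_a_min + (config.chm_island_a_max - config.chm_island_a_min) \
        * (1.0 - severity)
    b = config.chm_island_aspect * a
    residual = float(np.clip(
        rng.normal(config.chm_central_residual_mean, 1.0), DB_MIN, 6.0))
    return SensitivityField(
        profile=Group.CHOROIDEREMIA, peak_cyan=peak, peak_red=peak,
        radial_slope=slope, rod_free_radius=config.rod_free_radius,
        central_cyan_residual=residual,
        island_semi_axes=(a, b), island_center_offset=config.chm_island_offset,
        cyan_deficit=config.chm_cyan_deficit_base
        + config.chm_cyan_deficit_span * severity,
        red_deficit=config.chm_red_deficit_base
        + config.chm_red_deficit_span * severity,
    )


def simulate_cohort(config: SyntheticCohortConfig) -> list[SubjectRecord]:
    """Simulate a two-group cohort with test and same-day retest sessions.

    Fully reproducible from ``config.seed``: the same config always
    yields bit-identical cohorts.  Session test2 re-runs the staircases
    on the same true field with independent observer noise plus an
    additive per-locus perturbation of SD ``retest_sd_within``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    records: list[SubjectRecord] = []
    for group, prefix in ((Group.HEALTHY, "H"), (Group.CHOROIDEREMIA, "C")):
        for i in range(config.n_per_group):
            sid = f"{prefix}{i + 1:02d}"
            field = draw_field(config, group, rng)
            eye = Eye.OS if rng.random() < config.os_fraction else Eye.OD
            sigma = max(0.02, rng.normal(config.fixation_sigma_mean,
                                         config.fixation_sigma_sd))
            fixation = FixationModel(sigma, sigma, config.fixation_rho,
                                     config.fixation_n_samples)
            rec = SubjectRecord(sid, group,
                                island_area_mm2=field.island_area_mm2())
            sessions = (Session.TEST1, Session.TEST2) if config.with_retest \
                else (Session.TEST1,)
            for session in sessions:
                for color in config.colors:
                    # retest drift is drawn independently per color so the
                    # cyan and red within-subject variances add in the
                    # combined cyan-red index
                    offset = None
                    if session is Session.TEST2 and config.retest_sd_within > 0:
                        offset = rng.normal(0.0, config.retest_sd_within, len(grid))
                    rec.add(simulate_exam(
                        field, grid, config.observer, rng, color=color,
                        fixation=fixation, n_catch_trials=config.n_catch_trials,
                        subject_id=sid, eye=eye, session=session,
                        threshold_offset=offset,
                    ))
            records.append(rec)
    return records
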