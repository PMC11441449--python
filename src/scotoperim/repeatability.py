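"""Test-retest agreement: Bland-Altman models and the coefficient of
repeatability (CoR).

Pointwise sensitivities contribute many loci per participant, so naive
Bland-Altman limits computed from the pooled SD of all differences
conflate within- and between-participant variance.  The
:class:`RepeatedMeasuresBlandAltman` model instead fits a
random-intercept linear mixed-effects model to the test2 − test1
differences,

    d_ij = mu + u_i + e_ij,   u_i ~ N(0, sd_between^2),
                              e_ij ~ N(0, sd_within^2),

by REML, and derives

* CoR  = 2 x 1.96 x sd_within  (the smallest change exceeding
  test-retest variability — "clinical significance"),
* limits of agreement = mu +/- 1.96 x sqrt(sd_between^2 + sd_within^2),

with cluster-bootstrap (resampling participants) percentile confidence
intervals.  :class:`StandardBlandAltman` covers the one-pair-per-subject
case used for mean and volume sensitivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exam import Color, Condition, NON_SEEN, Session, SubjectRecord
from . import indices as _indices

Z95 = 1.96

COR_FORMULAS = {
    "classic": lambda sw: 2.0 * Z95 * sw,  # 2 x 1.96 x SD_within
    "sqrt2": lambda sw: Z95 * np.sqrt(2.0) * sw,  # 1.96 x sqrt(2) x SD_within
}


@dataclass(frozen=True)
class RepeatabilityResult:
    """Estimates from a Bland-Altman repeatability fit.

    All quantities are in the units of the analyzed index (dB for
    pointwise/mean sensitivity, dB·deg² for volume sensitivity).
    """

    bias: float
    sd_within: float
    sd_between: float
    cor: float
    loa_low: float
    loa_high: float
    n_subjects: int
    n_pairs: int
    cor_formula: str = "classic"
    model: str = "rm_bland_altman"
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.sd_within < 0 or self.sd_between < 0:
            raise ValueError("SD components must be >= 0")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")

    def summary(self) -> SimpleTable:
        rows = [
            ("bias (test2 - test1)", self.bias),
            ("sd_within", self.sd_within),
            ("sd_between", self.sd_between),
            (f"CoR ({self.cor_formula})", self.cor),
            ("LoA low", self.loa_low),
            ("LoA high", self.loa_high),
        ]
        data = []
        for name, value in rows:
            lo, hi = self.ci.get(_ci_key(name), (np.nan, np.nan))
            data.append([name, f"{value:.4g}",
                         "" if np.isnan(lo) else f"[{lo:.4g}, {hi:.4g}]"])
        title = (f"{self.model}: {self.n_subjects} subjects, "
                 f"{self.n_pairs} pairs, {self.n_boot} bootstrap reps")
        return SimpleTable(data, headers=["estimate", "value", "95% CI"],
                           title=title)


def _ci_key(name: str) -> str:
    return {"bias (test2 - test1)": "bias", "LoA low": "loa_low",
            "LoA high": "loa_high"}.get(name, name.split(" ")[0].lower())


def _as_paired_frame(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    required = {"subject", "value_test1", "value_test2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"paired measurements need columns {sorted(missing)}")
    if df[["value_test1", "value_test2"]].isna().any().any():
        raise ValueError("both session values must be present in every row")
    return df


def _variance_components(d: np.ndarray, subjects: np.ndarray) -> tuple[float, float, float]:
    """(bias, sd_within, sd_between) of differences via REML MixedLM."""
    bias = float(np.mean(d))
    if np.ptp(d) == 0.0:
        return bias, 0.0, 0.0
    groups, counts = np.unique(subjects, return_counts=True)
    if len(groups) < 2 or counts.max() < 2:
        # no replication within subject: all variance is within
        return bias, float(np.std(d, ddof=1)), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(endog=np.asarray(d, float),
                        exog=np.ones((len(d), 1)), groups=subjects)
        fit = model.fit(reml=True)
    bias = float(fit.fe_params[0])
    sd_within = float(np.sqrt(fit.scale))
    sd_between = float(np.sqrt(max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)))
    return bias, sd_within, sd_between


class RepeatedMeasuresBlandAltman:
    """Repeated-measures Bland-Altman model for paired measurements.

    Parameters
    ----------
    data
        DataFrame (or convertible) with columns ``subject``,
        ``value_test1``, ``value_test2`` and optionally ``unit``
        (locus id).  Requires >= 2 subjects and replication (>= 2 units)
        within at least one subject.
    """

    def __init__(self, data) -> None:
        df = _as_paired_frame(data)
        if df["subject"].nunique() < 2:
            raise ValueError("repeated-measures Bland-Altman requires >= 2 subjects")
        if df.groupby("subject").size().max() < 2:
            raise ValueError("requires >= 2 paired units within at least one subject")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject: str = "subject",
                       test1: str = "value_test1", test2: str = "value_test2",
                       unit: str | None = None) -> "RepeatedMeasuresBlandAltman":
        cols = {subject: "subject", test1: "value_test1", test2: "value_test2"}
        if unit is not None:
            cols[unit] = "unit"
        return cls(df.rename(columns=cols)[list(cols.values())])

    def fit(self, n_boot: int = 1000, seed: int | None = None,
            cor_formula: str = "classic") -> RepeatabilityResult:
        """Fit by REML; optional cluster bootstrap for percentile CIs.

        The bootstrap resamples subjects with replacement and refits;
        ``n_boot=0`` skips it.  A degenerate dataset (all differences
        identical) yields zero SD components rather than an error.
        """
        df = self.data
        d = (df["value_test2"] - df["value_test1"]).to_numpy(float)
        subjects = df["subject"].to_numpy()
        bias, sw, sb = _variance_components(d, subjects)
        cor_fn = COR_FORMULAS[cor_formula]
        total_sd = float(np.hypot(sw, sb))
        ci: dict[str, tuple[float, float]] = {}
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            uniq = np.unique(subjects)
            by_subject = {s: d[subjects == s] for s in uniq}
            stats = np.empty((n_boot, 4))
            for b in range(n_boot):
                chosen = rng.choice(uniq, size=len(uniq), replace=True)
                db = np.concatenate([by_subject[s] for s in chosen])
                sb_labels = np.repeat(np.arange(len(chosen)),
                                      [len(by_subject[s]) for s in chosen])
                m, w, v = _variance_components(db, sb_labels)
                t = float(np.hypot(w, v))
                stats[b] = (m, m - Z95 * t, m + Z95 * t, cor_fn(w))
            lo, hi = np.percentile(stats, [2.5, 97.5], axis=0)
            for i, key in enumerate(("bias", "loa_low", "loa_high", "cor")):
                ci[key] = (float(lo[i]), float(hi[i]))
        return RepeatabilityResult(
            bias=bias, sd_within=sw, sd_between=sb, cor=cor_fn(sw),
            loa_low=bias - Z95 * total_sd, loa_high=bias + Z95 * total_sd,
            n_subjects=int(df["subject"].nunique()), n_pairs=len(df),
            cor_formula=cor_formula, ci=ci, n_boot=n_boot,
        )


class StandardBlandAltman:
    """Classical Bland-Altman for one measurement pair per subject.

    With a single pair per subject the within-subject SD is
    SD(differences)/sqrt(2); the CoR follows the same formula as the
    repeated-measures model and the limits of agreement are
    bias +/- 1.96 x SD(differences).
    """

    def __init__(self, data) -> None:
        df = _as_paired_frame(data)
        if len(df) < 2:
            raise ValueError("standard Bland-Altman requires >= 2 subjects")
        if df["subject"].duplicated().any():
            raise ValueError("expected one row per subject")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject: str = "subject",
                       test1: str = "value_test1",
                       test2: str = "value_test2") -> "StandardBlandAltman":
        return cls(df.rename(columns={subject: "subject", test1: "value_test1",
                                      test2: "value_test2"})
                   [["subject", "value_test1", "value_test2"]])

    def fit(self, n_boot: int = 0, seed: int | None = None,
            cor_formula: str = "classic") -> RepeatabilityResult:
        df = self.data
        d = (df["value_test2"] - df["value_test1"]).to_numpy(float)
        bias = float(d.mean())
        sd_d = float(d.std(ddof=1))
        sw = sd_d / np.sqrt(2.0)
        cor_fn = COR_FORMULAS[cor_formula]
        ci: dict[str, tuple[float, float]] = {}
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(d), size=(n_boot, len(d)))
            db = d[idx]
            means = db.mean(axis=1)
            sds = db.std(axis=1, ddof=1)
            stats = np.column_stack([means, means - Z95 * sds, means + Z95 * sds,
                                     cor_fn(sds / np.sqrt(2.0))])
            lo, hi = np.percentile(stats, [2.5, 97.5], axis=0)
            for i, key in enumerate(("bias", "loa_low", "loa_high", "cor")):
                ci[key] = (float(lo[i]), float(hi[i]))
        return RepeatabilityResult(
            bias=bias, sd_within=sw, sd_between=0.0, cor=cor_fn(sw),
            loa_low=bias - Z95 * sd_d, loa_high=bias + Z95 * sd_d,
            n_subjects=len(df), n_pairs=len(df), cor_formula=cor_formula,
            model="standard_bland_altman", ci=ci, n_boot=n_boot,
        )


def rm_bland_altman(data, n_boot: int = 1000, seed: int | None = None,
                    cor_formula: str = "classic") -> RepeatabilityResult:
    """Functional wrapper: fit :class:`RepeatedMeasuresBlandAltman`."""
    return RepeatedMeasuresBlandAltman(data).fit(n_boot=n_boot, seed=seed,
                                                 cor_formula=cor_formula)


def standard_bland_altman(data, n_boot: int = 0, seed: int | None = None,
                          cor_formula: str = "classic") -> RepeatabilityResult:
    """Functional wrapper: fit :class:`StandardBlandAltman`."""
    return StandardBlandAltman(data).fit(n_boot=n_boot, seed=seed,
                                         cor_formula=cor_formula)


def pooled_sd_cor(data, cor_formula: str = "classic") -> float:
    """Naive CoR from the pooled SD of all differences (no mixed model).

    Provided as a diagnostic: whenever between-subject variance is
    present this overestimates the within-subject CoR, which is why the
    mixed model is required.
    """
    df = _as_paired_frame(data)
    d = (df["value_test2"] - df["value_test1"]).to_numpy(float)
    return COR_FORMULAS[cor_formula](float(d.std(ddof=1)))


def agreement_rates(data) -> tuple[float, float]:
    """(exact-match %, within +/-2 dB %) over pointwise pairs.

    Sentinels compare equal for the exact rate; differences for the
    +/-2 dB band use the raw exported values (non-seen included), as in
    device-output comparisons.
    """
    df = _as_paired_frame(data)
    t1 = df["value_test1"].to_numpy(float)
    t2 = df["value_test2"].to_numpy(float)
    exact = 100.0 * float(np.mean(t1 == t2))
    within = 100.0 * float(np.mean(np.abs(t2 - t1) <= 2.0))
    return exact, within


# ---------------------------------------------------------------------------
# Builders from subject records


def paired_pointwise(records: list[SubjectRecord], color: Color | str,
                     condition: Condition | str = Condition.SCOTOPIC,
                     sentinel: str = "keep") -> pd.DataFrame:
    """Pointwise test1/test2 pairs for one color across a cohort.

    ``sentinel``: "keep" leaves −1.0 values, "zero" maps them to 0.0,
    "exclude" drops loci non-seen in either session.
    """
    rows = []
    for rec in records:
        e1 = rec.get(condition, color, Session.TEST1)
        e2 = rec.get(condition, color, Session.TEST2)
        if e1 is None or e2 is None:
            continue
        for locus, t1, t2 in zip(e1.grid.loci, e1.thresholds, e2.thresholds):
            rows.append((rec.subject_id, locus.id, t1, t2))
    df = pd.DataFrame(rows, columns=["subject", "unit", "value_test1", "value_test2"])
    if sentinel == "zero":
        df[["value_test1", "value_test2"]] = \
            df[["value_test1", "value_test2"]].replace(NON_SEEN, 0.0)
    elif sentinel == "exclude":
        df = df[(df["value_test1"] != NON_SEEN) & (df["value_test2"] != NON_SEEN)]
    elif sentinel != "keep":
        raise ValueError("sentinel must be 'keep', 'zero' or 'exclude'")
    return df.reset_index(drop=True)


def paired_summary(records: list[SubjectRecord], color: Color | str,
                   index: str = "mean", central_excluded: bool = False,
                   condition: Condition | str = Condition.SCOTOPIC) -> pd.DataFrame:
    """One mean- or volume-sensitivity pair per subject."""
    if index not in ("mean", "volume"):
        raise ValueError("index must be 'mean' or 'volume'")
    rows = []
    for rec in records:
        e1 = rec.get(condition, color, Session.TEST1)
        e2 = rec.get(condition, color, Session.TEST2)
        if e1 is None or e2 is None:
            continue
        if index == "mean":
            v1 = _indices.mean_sensitivity(e1, central_excluded)
            v2 = _indices.mean_sensitivity(e2, central_excluded)
        else:
            v1 = _indices.volume_sensitivity(e1)
            v2 = _indices.volume_sensitivity(e2)
        rows.append((rec.subject_id, v1, v2))
    return pd.DataFrame(rows, columns=["subject", "value_test1", "value_test2"])


def cyan_red_combined_cor(
    records: list[SubjectRecord],
    exclusion: str = "methods",
    n_boot: int = 1000,
    seed: int | None = None,
    cor_formula: str = "classic",
) -> RepeatabilityResult:
    """CoR of the pointwise cyan − red difference index across retests.

    Builds the per-locus cyan − red difference within each session and
    fits the repeated-measures model to its session-to-session change.
    ``exclusion="methods"`` drops loci with a non-seen (< 0 dB) value
    in either color at either session; ``exclusion="results"`` is the
    stricter variant additionally dropping 0.0-dB values.
    """
    if exclusion not in ("methods", "results"):
        raise ValueError("exclusion must be 'methods' or 'results'")
    rows = []
    for rec in records:
        exams = {(c, s): rec.get(Condition.SCOTOPIC, c, s)
                 for c in (Color.CYAN, Color.RED)
                 for s in (Session.TEST1, Session.TEST2)}
        if any(e is None for e in exams.values()):
            continue
        arr = {k: e.threshold_array for k, e in exams.items()}
        keep = np.ones(len(arr[(Color.CYAN, Session.TEST1)]), dtype=bool)
        for a in arr.values():
            keep &= (a > 0.0) if exclusion == "results" else (a >= 0.0)
        d1 = arr[(Color.CYAN, Session.TEST1)] - arr[(Color.RED, Session.TEST1)]
        d2 = arr[(Color.CYAN, Session.TEST2)] - arr[(Color.RED, Session.TEST2)]
        ids = exams[(Color.CYAN, Session.TEST1)].grid.locus_ids
        for i in np.nonzero(keep)[0]:
            rows.append((rec.subject_id, int(ids[i]), float(d1[i]), float(d2[i])))
    if not rows:
        raise ValueError("no loci remain after the exclusion rule")
    df = pd.DataFrame(rows, columns=["subject", "unit", "value_test1", "value_test2"])
    return RepeatedMeasuresBlandAltman(df).fit(n_boot=n_boot, seed=seed,
                                               cor_formula=cor_formula)
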