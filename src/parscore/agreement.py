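"""Reliability and agreement statistics for repeated PAR ratings.

Implements the statistical toolkit of a method-comparison / reproducibility
study on a crossed design (subject x timepoint x method x rater x session):

* Dahlberg error of the method, ``sqrt(sum d_i^2 / 2n)`` over n duplicate
  pairs, and the minimum standard deviation (MSD) criterion — the error of
  the method should fall below the smaller of the two series' SDs.
* Intraclass correlation, two-way random effects, absolute agreement, single
  measures (ICC(2,1) in Shrout-Fleiss terms, ICC(A,1) in McGraw-Wong terms),
  with the F-based 95% confidence interval.  A stratum whose ratings are all
  identical (e.g. every post-treatment overjet score is 0) has no
  between-subject variance and the ICC is reported as *undefined* rather
  than NaN-propagated or forced to 1.
* Paired t-tests, Bland-Altman bias and 1.96-SD limits of agreement.
* Walter, Eliasziw & Donner's closed-form sample size for testing an ICC
  against a minimum acceptable value.
* A report builder that assembles the above per stratum in the layout of a
  published reliability table: intra-rater rows compare session 1 vs 2
  within rater/method, inter-rater rows compare the raters' second sessions.

All SDs use the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

#: marker value reported when between-subject variance is zero
ICC_UNDEFINED = "undefined"


# ---------------------------------------------------------------------------
# elementary statistics


def dahlberg_error(differences) -> float:
    """Dahlberg's error of the method over paired duplicate differences."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise InsufficientDataError("Dahlberg error needs >= 2 paired differences")
    return float(np.sqrt(np.sum(d**2) / (2.0 * d.size)))


def minimum_sd(series1, series2) -> float:
    """The smaller of the two series' sample SDs (the MSD criterion)."""
    s1 = np.asarray(series1, dtype=float)
    s2 = np.asarray(series2, dtype=float)
    if s1.size < 2 or s2.size < 2:
        raise InsufficientDataError("MSD needs >= 2 observations per series")
    return float(min(np.std(s1, ddof=1), np.std(s2, ddof=1)))


@dataclass(frozen=True)
class DahlbergResult:
    error: float
    n_pairs: int
    msd: float

    @property
    def passes_msd(self) -> bool:
        return self.error < self.msd


def dahlberg_vs_msd(series1, series2) -> DahlbergResult:
    """Error of the method for two repeated series, with the MSD criterion."""
    s1 = np.asarray(series1, dtype=float)
    s2 = np.asarray(series2, dtype=float)
    if s1.shape != s2.shape:
        raise DomainError("repeated series must have equal length")
    return DahlbergResult(
        error=dahlberg_error(s1 - s2),
        n_pairs=int(s1.size),
        msd=minimum_sd(s1, s2),
    )


@dataclass(frozen=True)
class ICCResult:
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    model_label: str
    n_subjects: int
    n_ratings: int

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    def __post_init__(self):
        if self.defined:
            if self.estimate > 1 + 1e-12:
                raise DomainError("ICC estimate cannot exceed 1")
            if self.ci_low is not None and not (
                self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9
            ):
                raise DomainError("ICC estimate must lie inside its CI")


def _mean_squares(Y: np.ndarray):
    n, k = Y.shape
    gm = Y.mean()
    row_means = Y.mean(axis=1, keepdims=True)
    col_means = Y.mean(axis=0, keepdims=True)
    msr = k * float(((row_means - gm) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - gm) ** 2).sum()) / (k - 1)
    mse = float(((Y - row_means - col_means + gm) ** 2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_reproducibility(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``matrix`` is subjects x repeated ratings (sessions or raters as columns).
    Returns the undefined marker when the ratings carry no between-subject
    variance (an all-constant matrix), mirroring how reliability tables
    annotate strata where every score is zero.
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise InsufficientDataError("ICC needs >= 2 subjects and >= 2 ratings per subject")
    n, k = Y.shape
    label = "ICC(2,1) two-way random, absolute agreement, single measures"

    if np.allclose(Y, Y.flat[0]):
        return ICCResult(None, None, None, f"{label} [{ICC_UNDEFINED}: no variance]", n, k)

    msr, msc, mse = _mean_squares(Y)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300 or msr < 1e-300:
        return ICCResult(None, None, None, f"{label} [{ICC_UNDEFINED}: no between-subject variance]", n, k)
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong 1996, eq. for ICC(A,1)); degrees of freedom of
    # the Satterthwaite approximation depend on the point estimate itself.
    ci_low = ci_high = None
    if n >= 3 and mse > 0:
        fj = msc / mse
        num_v = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        den_v = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = num_v / den_v
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        ci_low = float(min(ci_low, icc))
        ci_high = float(min(max(ci_high, icc), 1.0))
    return ICCResult(float(icc), ci_low, ci_high, label, n, k)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_difference: float
    n: int
    degenerate: bool = False  # all differences exactly zero


def paired_t(x, y) -> PairedTResult:
    """Paired-samples t-test (two-sided).

    All-zero differences give t = 0, p = 1 flagged degenerate (the test is
    vacuous, not significant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired series must be 1-D and of equal length")
    if x.size < 2:
        raise InsufficientDataError("paired t needs >= 2 pairs")
    d = x - y
    if np.all(d == 0):
        return PairedTResult(0.0, 1.0, 0.0, int(x.size), degenerate=True)
    t, p = stats.ttest_rel(x, y)
    return PairedTResult(float(t), float(p), float(d.mean()), int(x.size))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    #: per-pair ((x+y)/2, x-y) points for plotting
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)


def bland_altman(x, y, loa_factor: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement for two paired methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired series must be 1-D and of equal length")
    if x.size < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_factor * sd,
        loa_high=bias + loa_factor * sd,
        n=int(x.size),
        means=(x + y) / 2.0,
        differences=d,
    )


def walter_sample_size(
    rho0: float, rho1: float, alpha: float = 0.05, power: float = 0.80, k: int = 2
) -> int:
    """Minimum subjects to show the ICC exceeds ``rho0`` when it is ``rho1``.

    Closed form of Walter, Eliasziw & Donner for k ratings per subject with a
    two-sided significance level::

        n = 1 + 2k (z_{a/2} + z_b)^2 / [(k-1) (ln C0)^2],
        C0 = (1 + k t1)/(1 + k t0),  t = rho/(1-rho)

    rounded up to the next integer.
    """
    if not (0 <= rho0 < 1 and 0 < rho1 < 1):
        raise DomainError("reliabilities must lie in [0, 1)")
    if rho1 <= rho0:
        raise DomainError("expected reliability must exceed the minimum acceptable one")
    if k < 2:
        raise DomainError("need k >= 2 ratings per subject")
    z_a = stats.norm.ppf(1 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    theta0 = rho0 / (1 - rho0)
    theta1 = rho1 / (1 - rho1)
    c0 = (1 + k * theta1) / (1 + k * theta0)
    n = 1 + 2 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.ceil(n))


# ---------------------------------------------------------------------------
# stratified report (published reliability-table layout)

RATING_COLUMNS = ("subject", "timepoint", "method", "rater", "session", "trait", "value")


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one stratum of the crossed design."""

    trait: str
    timepoint: str
    comparison: str  # "intra_rater" | "inter_rater" | "method"
    method: str | None
    rater: str | None
    mean_sd: dict[str, tuple[float, float]]  # arm label -> (mean, sd)
    paired: PairedTResult
    icc: ICCResult
    dahlberg: DahlbergResult
    bland_altman: BlandAltmanResult


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RATING_COLUMNS) - set(records.columns)
    if missing:
        raise DomainError(f"rating table missing columns {sorted(missing)}")
    dup = records.duplicated(subset=[c for c in RATING_COLUMNS if c != "value"])
    if dup.any():
        raise DomainError(f"{int(dup.sum())} duplicate rating keys in table")
    return records


def _arm(records, subjects, **levels) -> np.ndarray | None:
    """Values of one design cell ordered by subject; None if incomplete."""
    sub = records
    for col, val in levels.items():
        sub = sub[sub[col] == val]
    sub = sub.set_index("subject")["value"]
    if not set(subjects) <= set(sub.index):
        return None
    return sub.loc[list(subjects)].to_numpy(dtype=float)


def _stratum_report(trait, tp, comparison, method, rater, arms) -> AgreementReport | None:
    (label1, s1), (label2, s2) = arms
    if s1 is None or s2 is None:
        return None
    return AgreementReport(
        trait=trait,
        timepoint=tp,
        comparison=comparison,
        method=method,
        rater=rater,
        mean_sd={
            label1: (float(np.mean(s1)), float(np.std(s1, ddof=1))),
            label2: (float(np.mean(s2)), float(np.std(s2, ddof=1))),
        },
        paired=paired_t(s1, s2),
        icc=icc_reproducibility(np.column_stack([s1, s2])),
        dahlberg=dahlberg_vs_msd(s1, s2),
        bland_altman=bland_altman(s1, s2),
    )


def build_agreement_report(records: pd.DataFrame, comparisons=("intra_rater", "inter_rater")) -> list[AgreementReport]:
    """One :class:`AgreementReport` per stratum of the crossed design.

    Intra-rater strata compare session 1 vs session 2 within each
    (trait, timepoint, method, rater).  Inter-rater strata compare rater I
    vs rater II using each rater's *second* session, within each
    (trait, timepoint, method).  Strata with incomplete cells are skipped.
    """
    records = _validate_records(records)
    subjects = sorted(records["subject"].unique())
    traits = sorted(records["trait"].unique())
    timepoints = sorted(records["timepoint"].unique())
    methods = sorted(records["method"].unique())
    raters = sorted(records["rater"].unique())
    sessions = sorted(records["session"].unique())
    reports: list[AgreementReport] = []

    for trait, tp in product(traits, timepoints):
        sub = records[(records["trait"] == trait) & (records["timepoint"] == tp)]
        if "intra_rater" in comparisons and len(sessions) >= 2:
            for method, rater in product(methods, raters):
                arms = [
                    (
                        f"session{s}",
                        _arm(sub, subjects, method=method, rater=rater, session=s),
                    )
                    for s in sessions[:2]
                ]
                rep = _stratum_report(trait, tp, "intra_rater", method, rater, arms)
                if rep:
                    reports.append(rep)
        if "inter_rater" in comparisons and len(raters) >= 2:
            second = sessions[-1]
            for method in methods:
                arms = [
                    (
                        f"rater_{r}",
                        _arm(sub, subjects, method=method, rater=r, session=second),
                    )
                    for r in raters[:2]
                ]
                rep = _stratum_report(trait, tp, "inter_rater", method, None, arms)
                if rep:
                    reports.append(rep)
        if "method" in comparisons and len(methods) >= 2:
            second = sessions[-1]
            for rater in raters:
                arms = [
                    (
                        m,
                        _arm(sub, subjects, method=m, rater=rater, session=second),
                    )
                    for m in methods[:2]
                ]
                rep = _stratum_report(trait, tp, "method", None, rater, arms)
                if rep:
                    reports.append(rep)
    return reports


def reports_to_frame(reports: list[AgreementReport]) -> pd.DataFrame:
    """Flatten reports into the columns of a published reliability table."""
    rows = []
    for r in reports:
        labels = list(r.mean_sd)
        row = {
            "trait": r.trait,
            "timepoint": r.timepoint,
            "comparison": r.comparison,
            "method": r.method,
            "rater": r.rater,
            "arm1": labels[0],
            "mean1": r.mean_sd[labels[0]][0],
            "sd1": r.mean_sd[labels[0]][1],
            "arm2": labels[1],
            "mean2": r.mean_sd[labels[1]][0],
            "sd2": r.mean_sd[labels[1]][1],
            "error_of_method": r.dahlberg.error,
            "msd": r.dahlberg.msd,
            "error_below_msd": r.dahlberg.passes_msd,
            "icc": r.icc.estimate if r.icc.defined else ICC_UNDEFINED,
            "icc_ci_low": r.icc.ci_low,
            "icc_ci_high": r.icc.ci_high,
            "t": r.paired.t,
            "p_value": r.paired.p,
            "bias": r.bland_altman.bias,
            "loa_low": r.bland_altman.loa_low,
            "loa_high": r.bland_altman.loa_high,
            "n_subjects": r.dahlberg.n_pairs,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_paired_tests"] = len(rows)  # no multiplicity correction applied
    df.attrs["msd_definition"] = "min of the two compared series' sample SDs (ddof=1)"
    return df
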