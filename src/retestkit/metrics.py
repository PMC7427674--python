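"""Per-region repeatability statistics.

Covers the descriptive half of a test-retest analysis: session means and
coefficients of variation, absolute intrasubject variability, Bland-Altman
bias and limits of agreement, and the minimum detectable difference (MDD).

Conventions
-----------
Differences are always test − retest. The MDD is the smallest change that
exceeds ~95% of the test-retest difference distribution; three common
conventions are implemented because published values mix them:

``sd_diff_sample``
    1.96 × sample SD (n−1 denominator) of the differences (default).
``sd_diff_population``
    1.96 × population SD (n denominator) of the differences.
``sem_based``
    1.96 × √2 × SEM, with SEM = √MS_E from the two-way ANOVA. For k = 2
    sessions this is algebraically identical to ``sd_diff_sample``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anova import sem_from_anova, two_way_anova
from .dataset import PairedMeasurements
from .errors import InsufficientDataError, UndefinedDenominatorError, ValidationError

__all__ = [
    "MDD_METHODS",
    "RepeatabilitySummary",
    "absolute_variability",
    "signed_variability",
    "coefficient_of_variation",
    "bland_altman",
    "bland_altman_table",
    "minimum_detectable_difference",
    "session_summary",
    "summarise_region",
]

MDD_METHODS = ("sd_diff_sample", "sd_diff_population", "sem_based")


@dataclass(frozen=True)
class RepeatabilitySummary:
    """One region's repeatability metrics (the descriptive report row)."""

    region_name: str
    n: int
    mean_test: float
    sd_test: float
    cov_test: float
    mean_retest: float
    sd_retest: float
    cov_retest: float
    absvar_per_subject: np.ndarray
    absvar_mean: float
    bias: float
    loa_low: float
    loa_high: float
    mdd: float
    mdd_method: str


def _require_pairs(pm: PairedMeasurements, n_min: int = 2) -> None:
    if pm.n < n_min:
        raise InsufficientDataError(
            f"region {pm.region_name!r}: need at least {n_min} pairs, got {pm.n}"
        )


def absolute_variability(pm: PairedMeasurements) -> tuple[np.ndarray, float]:
    """Absolute intrasubject variability, per subject and its mean.

    Per subject: |test − retest| / ((test + retest)/2) × 100. The summary
    value is the arithmetic mean over subjects, in percent.
    """
    means = pm.pair_means()
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        names = [pm.subject_ids[i] for i in bad]
        raise UndefinedDenominatorError(
            f"region {pm.region_name!r}: non-positive pair mean for subject(s) {names}"
        )
    per = np.abs(pm.differences()) / means * 100.0
    return per, float(per.mean())


def signed_variability(pm: PairedMeasurements) -> tuple[np.ndarray, float]:
    """Signed variant of :func:`absolute_variability` for bias inspection:
    (test − retest) / pair mean × 100, without the absolute value."""
    means = pm.pair_means()
    if np.any(means <= 0):
        raise UndefinedDenominatorError(
            f"region {pm.region_name!r}: non-positive pair mean"
        )
    per = pm.differences() / means * 100.0
    return per, float(per.mean())


def coefficient_of_variation(values: np.ndarray) -> float:
    """Coefficient of variation in percent: sample SD / mean × 100."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("COV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise UndefinedDenominatorError("COV undefined: mean is zero")
    return float(values.std(ddof=1) / mean * 100.0)


def bland_altman(
    pm: PairedMeasurements, multiplier: float = 1.96
) -> tuple[float, float, float]:
    """Bland-Altman bias and limits of agreement.

    Returns (bias, lower limit, upper limit) where bias is the mean
    test − retest difference and the limits are bias ± multiplier × sample
    SD of the differences. The conventional multiplier is 1.96; pass 2.0
    for the rounded "2 SD" variant some figures use.
    """
    _require_pairs(pm)
    d = pm.differences()
    bias = float(d.mean())
    spread = multiplier * float(d.std(ddof=1))
    return bias, bias - spread, bias + spread


def bland_altman_table(
    pm: PairedMeasurements, multiplier: float = 1.96
):
    """Plot-ready Bland-Altman data: per-subject pair means and differences
    plus the constant bias/limit lines, as a pandas DataFrame."""
    import pandas as pd

    bias, lo, hi = bland_altman(pm, multiplier)
    return pd.DataFrame(
        {
            "subject": pm.subject_ids,
            "pair_mean": pm.pair_means(),
            "difference": pm.differences(),
            "bias": bias,
            "loa_low": lo,
            "loa_high": hi,
        }
    )


def minimum_detectable_difference(
    pm: PairedMeasurements, method: str = "sd_diff_sample"
) -> float:
    """Minimum detectable difference under one of three conventions.

    See the module docstring for the conventions; units are those of the
    measurements (BP_ND for PET binding data).
    """
    _require_pairs(pm)
    d = pm.differences()
    if method == "sd_diff_sample":
        return float(1.96 * d.std(ddof=1))
    if method == "sd_diff_population":
        return float(1.96 * d.std(ddof=0))
    if method == "sem_based":
        return float(1.96 * np.sqrt(2.0) * sem_from_anova(two_way_anova(pm)))
    raise ValidationError(
        f"unknown MDD method {method!r}; choose one of {MDD_METHODS}"
    )


def session_summary(
    pm: PairedMeasurements,
) -> tuple[float, float, float, float]:
    """Per-session mean and sample SD: (mean_test, sd_test, mean_retest, sd_retest)."""
    _require_pairs(pm)
    t, r = pm.test_values, pm.retest_values
    return (
        float(t.mean()),
        float(t.std(ddof=1)),
        float(r.mean()),
        float(r.std(ddof=1)),
    )


def summarise_region(
    pm: PairedMeasurements,
    mdd_method: str = "sd_diff_sample",
    ba_multiplier: float = 1.96,
) -> RepeatabilitySummary:
    """Bundle all descriptive repeatability metrics for one region."""
    mean_t, sd_t, mean_r, sd_r = session_summary(pm)
    per, absvar_mean = absolute_variability(pm)
    bias, lo, hi = bland_altman(pm, ba_multiplier)
    return RepeatabilitySummary(
        region_name=pm.region_name,
        n=pm.n,
        mean_test=mean_t,
        sd_test=sd_t,
        cov_test=coefficient_of_variation(pm.test_values),
        mean_retest=mean_r,
        sd_retest=sd_r,
        cov_retest=coefficient_of_variation(pm.retest_values),
        absvar_per_subject=per,
        absvar_mean=absvar_mean,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        mdd=minimum_detectable_difference(pm, mdd_method),
        mdd_method=mdd_method,
    )
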