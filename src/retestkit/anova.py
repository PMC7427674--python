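"""Two-way random-effects ANOVA and the absolute-agreement ICC.

The reliability model treats subjects and sessions (trials) as crossed
random effects. With n subjects measured in k trials, the decomposition of
the subject × trial table yields three mean squares — between subjects
(MS_S), between trials (MS_T), and error (MS_E) — from which the
single-measurement absolute-agreement intraclass correlation, ICC(2,1) in
the Shrout–Fleiss taxonomy and ICC(A,1) in McGraw & Wong's, is

    ICC = (MS_S − MS_E) / (MS_S + (k−1)·MS_E + k·(MS_T − MS_E)/n)

Absolute agreement charges any systematic session effect (MS_T) against
reliability, which is the appropriate choice for test-retest designs
where a session bias is a real measurement problem.

Confidence intervals use the McGraw & Wong (1996) F-distribution method
with Satterthwaite degrees of freedom for the lower-tail pivot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import PairedMeasurements
from .errors import DegenerateVarianceError, InsufficientDataError, ValidationError

__all__ = [
    "AnovaDecomposition",
    "ReliabilityEstimate",
    "two_way_anova",
    "icc_agreement",
    "icc_consistency",
    "icc_confidence_interval",
    "sem_from_anova",
    "interpret_icc",
]


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares and degrees of freedom of the two-way decomposition."""

    ms_subjects: float
    ms_trials: float
    ms_error: float
    n_subjects: int
    n_trials: int
    grand_mean: float

    @property
    def df_subjects(self) -> int:
        return self.n_subjects - 1

    @property
    def df_trials(self) -> int:
        return self.n_trials - 1

    @property
    def df_error(self) -> int:
        return (self.n_subjects - 1) * (self.n_trials - 1)


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Point estimate, confidence interval and qualitative band for an ICC."""

    icc: float
    ci_low: float
    ci_high: float
    ci_level: float
    interpretation: str


def two_way_anova(pm: PairedMeasurements | np.ndarray) -> AnovaDecomposition:
    """Decompose a subjects × trials table into the three mean squares.

    Accepts a :class:`PairedMeasurements` (k = 2) or any n × k array with
    k ≥ 2 trials. Sums of squares follow the textbook definitions:
    SS_S = k·Σᵢ(row meanᵢ − grand mean)², SS_T = n·Σⱼ(column meanⱼ − grand
    mean)², and SS_E is the remainder of the total sum of squares.
    """
    if isinstance(pm, PairedMeasurements):
        table = np.column_stack([pm.test_values, pm.retest_values])
    else:
        table = np.asarray(pm, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValidationError("expected an n x k table with k >= 2 trials")
    n, k = table.shape
    if n < 2:
        raise InsufficientDataError(f"need at least 2 subjects, got {n}")
    if not np.isfinite(table).all():
        raise ValidationError("non-finite values in measurement table")

    grand = table.mean()
    ss_s = k * float(((table.mean(axis=1) - grand) ** 2).sum())
    ss_t = n * float(((table.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_e = max(ss_total - ss_s - ss_t, 0.0)  # guard tiny negative round-off
    return AnovaDecomposition(
        ms_subjects=ss_s / (n - 1),
        ms_trials=ss_t / (k - 1),
        ms_error=ss_e / ((n - 1) * (k - 1)),
        n_subjects=n,
        n_trials=k,
        grand_mean=grand,
    )


def interpret_icc(icc: float) -> str:
    """Qualitative reliability band: <0.5 low, 0.5–0.75 moderate,
    0.75–0.9 good, >0.9 excellent."""
    if icc < 0.5:
        return "low"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def _icc_point(anova: AnovaDecomposition) -> float:
    n, k = anova.n_subjects, anova.n_trials
    denom = (
        anova.ms_subjects
        + (k - 1) * anova.ms_error
        + k * (anova.ms_trials - anova.ms_error) / n
    )
    if denom == 0.0:
        raise DegenerateVarianceError(
            "all values identical: ICC denominator is zero"
        )
    return (anova.ms_subjects - anova.ms_error) / denom


def icc_agreement(
    anova: AnovaDecomposition, ci_level: float = 0.95
) -> ReliabilityEstimate:
    """Single-measurement absolute-agreement ICC with its F-method CI.

    Negative estimates are possible (MS_S < MS_E) and are reported as
    computed; the interpretation band for any negative value is "low".
    """
    icc = _icc_point(anova)
    lo, hi = icc_confidence_interval(anova, level=ci_level)
    return ReliabilityEstimate(
        icc=icc, ci_low=lo, ci_high=hi, ci_level=ci_level,
        interpretation=interpret_icc(icc),
    )


def icc_consistency(anova: AnovaDecomposition) -> float:
    """Single-measurement consistency ICC, ICC(C,1) = ICC(3,1).

    Ignores the trial effect; provided as a thin variant for comparison
    with the default absolute-agreement form.
    """
    k = anova.n_trials
    denom = anova.ms_subjects + (k - 1) * anova.ms_error
    if denom == 0.0:
        raise DegenerateVarianceError("all values identical")
    return (anova.ms_subjects - anova.ms_error) / denom


def icc_confidence_interval(
    anova: AnovaDecomposition, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided CI for the absolute-agreement single-measurement ICC.

    McGraw & Wong (1996) F-based interval: the upper-tail pivot uses
    F(df_subjects, ν) with Satterthwaite ν computed at the point estimate;
    bounds are clipped to [−1, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"ci level must be in (0, 1), got {level}")
    icc = _icc_point(anova)
    n, k = anova.n_subjects, anova.n_trials
    msr, msc, mse = anova.ms_subjects, anova.ms_trials, anova.ms_error

    alpha = 1.0 - level
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: the F pivots degenerate and the interval is {1}
        return 1.0, 1.0

    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        nu = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        nu = (n - 1.0) * (k - 1.0)

    f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, nu)
    f_hi = stats.f.ppf(1.0 - alpha / 2.0, nu, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return float(np.clip(lower, -1.0, 1.0)), float(np.clip(upper, -1.0, 1.0))


def sem_from_anova(anova: AnovaDecomposition) -> float:
    """Standard error of measurement: √MS_E, the within-subject SD of a
    single measurement."""
    return float(np.sqrt(anova.ms_error))
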