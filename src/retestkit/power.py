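"""Paired-design power analysis via the noncentral t distribution.

For a within-subject change delta tested with a paired t-test on n
subjects whose differences have standard deviation sd_diff, the test
statistic under the alternative follows a noncentral t distribution with
df = n − 1 and noncentrality delta·√n / sd_diff. Power is computed exactly
from that distribution — no normal approximation, which matters at the
small n (~9) typical of PET test-retest studies.

The detectable-change solver inverts the power function: given alpha,
target power and the observed sd_diff, it finds the smallest true change
detectable, and expresses it as a percent of the region's pooled
test/retest mean (negative sign: a decline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import SolverError, ValidationError

__all__ = [
    "PowerQuery",
    "PowerResult",
    "bonferroni_alpha",
    "paired_power",
    "detectable_change",
    "sample_size_curve",
]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a paired-design power question.

    ``sd_diff`` is the SD of paired differences (same units as the
    measurements); ``baseline_mean`` the reference level used to express
    changes in percent; ``sides`` is "one" or "two".
    """

    n_subjects: int
    sd_diff: float
    baseline_mean: float
    alpha: float = 0.0125
    power: float = 0.8
    sides: str = "one"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValidationError(f"power must be in (0, 1), got {self.power}")
        if self.n_subjects < 2:
            raise ValidationError(f"need n >= 2 subjects, got {self.n_subjects}")
        if self.sd_diff <= 0:
            raise ValidationError(f"sd_diff must be > 0, got {self.sd_diff}")
        if self.baseline_mean <= 0:
            raise ValidationError(
                f"baseline_mean must be > 0, got {self.baseline_mean}"
            )
        if self.sides not in ("one", "two"):
            raise ValidationError(f"sides must be 'one' or 'two', got {self.sides!r}")


@dataclass(frozen=True)
class PowerResult:
    """Detectable change in absolute units and as percent of baseline."""

    detectable_abs: float
    detectable_pct: float
    achieved_power: float


def bonferroni_alpha(alpha: float = 0.05, m: int = 4) -> float:
    """Per-comparison significance level alpha/m (e.g. 0.05/4 = 0.0125)."""
    if m < 1:
        raise ValidationError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def paired_power(delta: float, query: PowerQuery) -> float:
    """Exact power of the paired t-test at true mean difference ``delta``.

    At delta = 0 the returned value equals alpha: the test is size-correct.
    """
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    n = query.n_subjects
    df = n - 1
    nc = delta * np.sqrt(n) / query.sd_diff
    if query.sides == "two":
        crit = stats.t.ppf(1.0 - query.alpha / 2.0, df)
        power = stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
    else:
        crit = stats.t.ppf(1.0 - query.alpha, df)
        power = stats.nct.sf(crit, df, nc)
    if np.isnan(power):  # scipy's nct underflows at extreme noncentrality
        power = stats.norm.sf(crit - nc)
    return float(power)


def detectable_change(query: PowerQuery) -> PowerResult:
    """Smallest within-subject change detectable at the requested power.

    Solves paired_power(delta) = power for delta by bracketing + Brent's
    method (tolerance 1e-8 in delta); power is strictly increasing in
    delta so the root is unique. The percent change is reported relative
    to ``baseline_mean`` with a negative sign, the convention for a
    decline in binding.
    """
    target = query.power

    def gap(delta: float) -> float:
        return paired_power(delta, query) - target

    hi = query.sd_diff
    for _ in range(60):
        if gap(hi) > 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable given monotonicity
        raise SolverError("could not bracket the detectable change")
    delta = float(optimize.brentq(gap, 0.0, hi, xtol=1e-8))
    return PowerResult(
        detectable_abs=delta,
        detectable_pct=-100.0 * delta / query.baseline_mean,
        achieved_power=paired_power(delta, query),
    )


def sample_size_curve(
    effect_pct_grid: np.ndarray,
    query: PowerQuery,
    n_cap: int = 10_000,
) -> pd.DataFrame:
    """Required sample size for each effect size on a grid.

    For each percent effect (of ``baseline_mean``), the smallest integer
    n ≥ 2 whose paired-t power reaches the requested power. Effects so
    small that n would exceed ``n_cap`` are reported with ``censored=True``
    and n = <NA> rather than raising.

    Returns a DataFrame with columns effect_pct, required_n, censored.
    """
    grid = np.asarray(effect_pct_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValidationError("effect sizes must be positive percentages")

    rows = []
    for pct in grid:
        delta = pct / 100.0 * query.baseline_mean

        def power_at(n: int) -> float:
            return paired_power(delta, replace(query, n_subjects=n))

        if power_at(n_cap) < query.power:
            rows.append((pct, pd.NA, True))
            continue
        lo, hi = 2, 2
        while power_at(hi) < query.power:
            lo, hi = hi, min(hi * 2, n_cap)
        while lo < hi:  # binary search for the smallest adequate n
            mid = (lo + hi) // 2
            if power_at(mid) >= query.power:
                hi = mid
            else:
                lo = mid + 1
        rows.append((pct, lo, False))
    out = pd.DataFrame(rows, columns=["effect_pct", "required_n", "censored"])
    out["required_n"] = out["required_n"].astype("Int64")
    return out
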