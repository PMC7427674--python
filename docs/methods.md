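# Methods

## Model

A test-retest study measures each of n subjects twice under identical
conditions. retestkit models the measurement as

    y_ij = mu + s_i + t_j + e_ij,   i = 1..n subjects, j = 1..k sessions,

with random subject effects s_i ~ N(0, sigma_b²), random session (trial)
effects t_j, and i.i.d. error e_ij ~ N(0, sigma_w²). The two-way ANOVA of
the n × k table gives mean squares MS_S (subjects), MS_T (trials) and
MS_E (error); the single-measurement absolute-agreement intraclass
correlation is

    ICC(2,1) = (MS_S − MS_E) / (MS_S + (k−1)·MS_E + k·(MS_T − MS_E)/n).

Absolute agreement charges session effects against reliability, which is
what a longitudinal biomarker needs: a scanner or calibration drift
between sessions is a real error. A consistency variant, ICC(C,1), is
exposed for comparison but is not the default. k is fixed at 2 by the
data model, but the formulas are implemented for general k ≥ 2.

Interpretation bands follow the common clinical convention: < 0.5 low,
0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent. Negative ICC
estimates are mathematically possible (MS_S < MS_E) and are reported as
computed, labelled "low"; they are not truncated at zero. All-identical
data raise an explicit degenerate-variance error rather than returning
NaN.

## Confidence intervals

The CI method is the F-distribution interval of McGraw & Wong (1996) for
ICC(A,1), with Satterthwaite degrees of freedom evaluated at the point
estimate and bounds clipped to [−1, 1]. This is the method behind the
common implementations (e.g. pingouin, the irr family). Published
intervals computed with other approximations can differ by several
hundredths in the lower bound at small n, especially for low-ICC regions;
agreement with such values is therefore tolerance-based, not exact.

## Repeatability metrics

- **Absolute intrasubject variability**: per subject
  |test − retest| / pair mean × 100; the summary is the arithmetic mean
  over subjects (not the median). The absolute value is part of the
  definition — the quantity is a magnitude; a signed variant is exposed
  separately for bias inspection. Undefined (error, not NaN) when a pair
  mean is ≤ 0.
- **COV**: sample SD (n−1) / mean × 100 per session.
- **Bland-Altman**: differences are always test − retest; limits are
  bias ± 1.96 × sample SD of differences by default, with a 2.0
  multiplier option matching the rounded "2 SD" convention some figures
  use.
- **Minimum detectable difference**: the smallest change exceeding ~95%
  of test-retest difference variability. Published values mix at least
  two conventions, so three are implemented and all reported:
  1.96 × sample SD of differences (default), 1.96 × population SD, and
  1.96·√2·SEM with SEM = √MS_E. For k = 2 the SEM-based and sample-SD
  forms are algebraically identical (MS_E = s_d²/2 regardless of the
  session effect), which the suite tests as an invariant.

## Power analysis

Detectable within-subject change uses the exact paired-t power: under a
true change delta the test statistic is noncentral t with df = n − 1 and
noncentrality delta·√n/sd_diff. No normal approximation is used — at
n ≈ 9 the difference is material. The detectable change solves
power(delta) = target by bracketing plus Brent's method (tolerance 1e-8);
power is strictly increasing in delta, so the root is unique. Percent
change is expressed relative to the pooled test/retest grand mean of the
region, negative for a decline.

Defaults: alpha 0.0125 (a Bonferroni 0.05/4 for four primary regions),
power 0.8, **one-sided**, sample-SD of differences as the effect-size
denominator. One-sided is the package default because a longitudinal
decline hypothesis in a degenerative disease is directional, and because
this convention reproduces the published detectable-change column of the
bundled dataset exactly in all five regions; the two-sided variant is a
flag away. The sample-size curve inverts the same power function for the
smallest adequate integer n, with effects too small for a configurable
n-cap reported as censored rather than raised.

## Synthetic data

The generator draws subject true values T_i ~ N(mu, sigma_b²) and
sessions T_i + e (test), T_i + bias + e (retest) with
e ~ N(0, sigma_w²) — exactly the variance structure the ICC model
presumes, so the population ICC is known:

    ICC_pop = sigma_b² / (sigma_b² + sigma_w² + bias²/2).

Defaults (n = 9, mu = 1.5, sigma_b = 0.35, sigma_w = 0.08, bias = 0)
emulate the striatum of a small PD DAT-PET study: between-subject COV
~23% and test-retest variability ~6%. A multiplicative (log-normal)
error mode is included because PET outcome variability often scales with
binding, but it is off by default since the ICC model assumes additive
homoscedastic error.

What the generator does *not* emulate: regional correlation within
subject (regions are generated independently), disease progression,
scanner drift beyond a constant session bias, or the truncation of
binding potential at zero — with a large sigma_b/mu ratio a simulated
subject can cross zero, in which case AbsVar is undefined and the
recovery experiment records that replicate as missing for AbsVar only.
Passing parameter-recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to real
PET artefacts.

Seeding: one integer seed fully determines a dataset; replicate r of a
recovery experiment uses seed + r.

## Reference dataset and the exclusion

The packaged dataset holds the published individual BP_ND values at
printed precision (3 decimals); nothing is rounded or rescaled on
ingest, and a SHA-256 checksum of the canonical serialisation guards the
file. The main analysis excludes subject 8: that subject's two PET scans
shared one transmission scan, biasing attenuation correction in the
reference region. The identity of the excluded subject is derivable from
the data — it is the unique single-subject exclusion under which the
striatum test-session mean of the remaining nine equals the published
1.55 — and the test suite performs that brute-force derivation.

## Numerical choices and problem sizes

Display rounding (means 2 d.p., COV/AbsVar 1 d.p., ICC 2 d.p., MDD
3 d.p.) is applied only in the formatted report; machine-readable output
always carries full precision. The scipy noncentral-t survival function
underflows to NaN at extreme noncentrality; power falls back to the
normal limit there, which is exact in that regime.

Monte-Carlo test sizes were chosen so each check's sampling error is
well below its assertion tolerance: 10,000 subjects for Bland-Altman
coverage, 50,000 for the folded-normal AbsVar expectation, 200
replicates of 500 subjects for ICC recovery (estimator SE ≈ 0.0004
against a ±0.01 band), and 60–100 seeds for ordering properties that
must hold in ≥ 95% of draws.

## Known limitations

- Strictly two sessions per subject in the data model; the ANOVA core
  accepts general k but nothing upstream produces it.
- No proportional-bias (regression-based) Bland-Altman extension.
- No two-sample or mixed-model power; the power module answers only the
  paired within-subject question.
- CI coverage of the F-method at n = 9 is approximate; simulation-based
  intervals are out of scope.
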