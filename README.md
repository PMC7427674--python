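# retestkit

Test-retest reliability and repeatability analysis for paired regional
outcome measures, built around the statistics used to qualify an imaging
biomarker: the two-way random-effects intraclass correlation, absolute
intrasubject variability, the minimum detectable difference, Bland-Altman
agreement, and the within-subject change detectable at a given power in a
paired design.

The package ships a complete worked dataset: individual non-displaceable
binding potential (BP_ND) values of the dopamine transporter PET ligand
[18F]FE-PE2I in ten patients with Parkinson's disease, each scanned twice,
in five brain regions (striatum, caudate, putamen, ventral striatum,
substantia nigra). It is aimed at anyone running a test-retest study of a
quantitative regional measure — PET binding, volumetry, perfusion — who
needs the reliability table and the power implications from a single
command.

## The statistics

Each region's n subjects × 2 sessions table is decomposed by two-way
ANOVA into subject, trial and error mean squares (MS_S, MS_T, MS_E). The
single-measurement absolute-agreement ICC — ICC(2,1) in the Shrout–Fleiss
taxonomy — is

    ICC = (MS_S − MS_E) / (MS_S + (k−1)·MS_E + k·(MS_T − MS_E)/n),   k = 2,

with F-method (McGraw & Wong 1996) confidence intervals. Alongside it:

- **AbsVar** = |test − retest| / pair mean × 100, averaged over subjects;
- **COV** = SD/mean × 100 per session;
- **MDD** = 1.96 × SD of the paired differences (sample-SD, population-SD
  and SEM-based conventions are all reported, since published values mix
  them);
- **Bland-Altman** bias and limits of agreement;
- **powered detectable change**: the smallest within-subject change a
  paired t-test detects at a chosen power, from the exact noncentral-t
  distribution, expressed as a percent decline of the region mean.

A synthetic-data module generates paired datasets with known
between-subject SD, within-subject SD and session bias, so every
estimator can be validated by parameter recovery.

## Worked example

The main analysis of the bundled dataset excludes subject 8, whose two
scans shared a single transmission scan (a bias in the attenuation
correction of the reference region):

```sh
retestkit fixture --out ref.csv
retestkit compute ref.csv --exclude 8
```

prints

```
          region  n  mean_test  sd_test  cov_test  mean_retest  sd_retest  cov_retest  absvar_mean  icc  icc_ci_low  icc_ci_high   mdd  detectable_pct
        striatum  9       1.55     0.33      21.1         1.56       0.32        20.5          5.3 0.95        0.80         0.99 0.206            -8.3
         caudate  9       1.84     0.55      29.9         1.88       0.59        31.4          6.0 0.97        0.89         0.99 0.265            -8.9
         putamen  9       1.26     0.32      25.3         1.25       0.22        17.8          7.5 0.91        0.66         0.98 0.237           -11.9
ventral striatum  9       2.21     0.53      23.9         2.13       0.38        17.9          6.5 0.89        0.61         0.97 0.420           -12.1
substantia nigra  9       0.72     0.17      23.2         0.72       0.10        14.5         10.6 0.74        0.17         0.94 0.206           -17.9
```

Reading the striatum row: the two sessions agree to 5.3% within subjects;
95% of the variance across subjects is true between-patient difference
(ICC 0.95, "excellent"); a change larger than 0.206 BP_ND exceeds 95% of
test-retest noise; and with nine patients a true decline of 8.3% or more
is detectable at 80% power (one-sided, alpha 0.0125 = 0.05/4 Bonferroni).
The substantia nigra — small, low-binding — is noisier: AbsVar 10.6%, ICC
0.74 ("moderate"), detectable change −17.9%.

The same is available in Python:

```python
import retestkit as rk

ds = rk.load_fe_pe2i_pd().apply_exclusion("8", "shared transmission scan")
report = rk.compute_report(ds)          # full-precision DataFrame in report.rows
print(rk.format_report(report))
```

`retestkit simulate` writes synthetic datasets, and `retestkit power`
prints detectable-change and sample-size–vs–effect tables for planning.

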