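"""Two-way ANOVA decomposition and the absolute-agreement ICC.

The independent oracle used throughout is a deliberately naive
loop-based variance-components computation from raw sums of squares,
coded separately from the vectorised implementation.
"""

import numpy as np
import pytest

import retestkit as rk
from retestkit.errors import DegenerateVarianceError, InsufficientDataError

from conftest import random_pairs


def naive_icc_from_raw_sums(table):
    """Method-of-moments ICC(2,1) via variance components, written as
    plain loops over the cells — the cross-check oracle."""
    n = len(table)
    k = len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_s = k * sum((m - grand) ** 2 for m in row_means)
    ss_t = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_s = ss_s / (n - 1)
    ms_t = ss_t / (k - 1)
    ms_e = (ss_tot - ss_s - ss_t) / ((n - 1) * (k - 1))
    var_subject = (ms_s - ms_e) / k
    var_trial = (ms_t - ms_e) / n
    return var_subject / (var_subject + var_trial + ms_e)


def pm_from_columns(test, retest):
    test = np.asarray(test, float)
    return rk.PairedMeasurements(
        "x", tuple(str(i) for i in range(len(test))), test, retest
    )


class TestTwoWayAnova:
    def test_duplicated_sessions(self):
        pm = pm_from_columns([1.0, 2.0], [1.0, 2.0])
        an = rk.two_way_anova(pm)
        assert an.ms_error == 0.0
        assert an.ms_trials == 0.0
        assert an.ms_subjects == pytest.approx(1.0)
        assert (an.df_subjects, an.df_trials, an.df_error) == (1, 1, 1)

    def test_all_identical_gives_zero_mean_squares(self):
        an = rk.two_way_anova(pm_from_columns([2.0] * 4, [2.0] * 4))
        assert an.ms_subjects == an.ms_trials == an.ms_error == 0.0

    def test_striatum_error_mean_square(self, striatum9):
        """Hand ANOVA over the 18 retained striatum values."""
        an = rk.two_way_anova(striatum9)
        assert an.ms_error == pytest.approx(0.0055443889, abs=1e-9)

    def test_sum_of_squares_reconstruction(self, rng):
        for n in (2, 5, 9, 30):
            pm = random_pairs(rng, n)
            an = rk.two_way_anova(pm)
            table = np.column_stack([pm.test_values, pm.retest_values])
            ss_total = ((table - table.mean()) ** 2).sum()
            recon = (
                an.ms_subjects * an.df_subjects
                + an.ms_trials * an.df_trials
                + an.ms_error * an.df_error
            )
            assert recon == pytest.approx(ss_total, rel=1e-9)

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            rk.two_way_anova(pm_from_columns([1.0], [1.1]))

    def test_general_k(self, rng):
        table = rng.normal(1.0, 0.3, size=(6, 4))
        an = rk.two_way_anova(table)
        assert an.n_trials == 4
        assert rk.icc_agreement(an).icc == pytest.approx(
            naive_icc_from_raw_sums(table.tolist()), abs=1e-10
        )


class TestIccPoint:
    def test_reference_regions(self, main_dataset):
        expected = {"striatum": 0.95, "substantia nigra": 0.74}
        for region, icc2dp in expected.items():
            est = rk.icc_agreement(rk.two_way_anova(main_dataset.region(region)))
            assert round(est.icc, 2) == icc2dp

    def test_perfect_agreement(self):
        est = rk.icc_agreement(rk.two_way_anova(pm_from_columns([1.0, 2.0], [1.0, 2.0])))
        assert est.icc == 1.0
        assert est.interpretation == "excellent"

    def test_degenerate_raises_not_nan(self):
        with pytest.raises(DegenerateVarianceError):
            rk.icc_agreement(rk.two_way_anova(pm_from_columns([2.0] * 3, [2.0] * 3)))

    def test_oracle_equivalence_on_random_instances(self, rng):
        """Printed-formula ICC equals the independent variance-components
        route on 100 random small instances."""
        for _ in range(100):
            n = int(rng.integers(2, 11))
            pm = random_pairs(rng, n)
            ours = rk.icc_agreement(rk.two_way_anova(pm)).icc
            table = np.column_stack([pm.test_values, pm.retest_values]).tolist()
            assert ours == pytest.approx(naive_icc_from_raw_sums(table), abs=1e-10)

    def test_pingouin_cross_check(self, striatum9):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": list(striatum9.subject_ids) * 2,
                "session": ["test"] * striatum9.n + ["retest"] * striatum9.n,
                "value": np.concatenate(
                    [striatum9.test_values, striatum9.retest_values]
                ),
            }
        )
        table = pg.intraclass_corr(
            df, targets="subject", raters="session", ratings="value"
        ).set_index("Type")
        ours = rk.icc_agreement(rk.two_way_anova(striatum9))
        assert ours.icc == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-10)

    def test_translation_invariance(self, rng):
        for shift in (-3.0, 0.7, 250.0):
            pm = random_pairs(rng, 8)
            shifted = pm_from_columns(pm.test_values + shift, pm.retest_values + shift)
            a = rk.icc_agreement(rk.two_way_anova(pm)).icc
            b = rk.icc_agreement(rk.two_way_anova(shifted)).icc
            assert abs(a - b) < 1e-12

    def test_scale_invariance(self, rng):
        for scale in (0.02, 3.0, 1e4):
            pm = random_pairs(rng, 8)
            scaled = pm_from_columns(pm.test_values * scale, pm.retest_values * scale)
            a = rk.icc_agreement(rk.two_way_anova(pm)).icc
            b = rk.icc_agreement(rk.two_way_anova(scaled)).icc
            assert abs(a - b) < 1e-12

    def test_session_bias_strictly_lowers_agreement(self, rng):
        """Absolute agreement penalises a trial effect: starting from data
        with equal session means, adding a constant to the retest strictly
        lowers the ICC."""
        pm = random_pairs(rng, 12)
        centred = pm_from_columns(
            pm.test_values - pm.test_values.mean(),
            pm.retest_values - pm.retest_values.mean(),
        )
        base = rk.icc_agreement(rk.two_way_anova(centred)).icc
        for bias in (0.05, -0.1, 0.3):
            biased = pm_from_columns(
                centred.test_values, centred.retest_values + bias
            )
            assert rk.icc_agreement(rk.two_way_anova(biased)).icc < base

    def test_icc_at_most_one_and_equality_condition(self, rng):
        for _ in range(50):
            pm = random_pairs(rng, int(rng.integers(2, 12)))
            an = rk.two_way_anova(pm)
            icc = rk.icc_agreement(an).icc
            assert icc <= 1.0
            assert (icc == 1.0) == (
                an.ms_error == 0.0 and an.ms_trials == 0.0 and an.ms_subjects > 0
            )

    def test_interpretation_bands(self):
        assert rk.interpret_icc(-0.2) == "low"
        assert rk.interpret_icc(0.49) == "low"
        assert rk.interpret_icc(0.6) == "moderate"
        assert rk.interpret_icc(0.8) == "good"
        assert rk.interpret_icc(0.95) == "excellent"

    def test_consistency_variant_ignores_session_bias(self, rng):
        pm = random_pairs(rng, 10)
        biased = pm_from_columns(pm.test_values, pm.retest_values + 0.4)
        a = rk.icc_consistency(rk.two_way_anova(pm))
        b = rk.icc_consistency(rk.two_way_anova(biased))
        assert a == pytest.approx(b, abs=1e-12)


class TestIccConfidenceInterval:
    def test_striatum_matches_published_bounds(self, striatum9):
        lo, hi = rk.icc_confidence_interval(rk.two_way_anova(striatum9))
        assert lo == pytest.approx(0.82, abs=0.02)
        assert hi == pytest.approx(0.989, abs=0.02)

    def test_interval_brackets_estimate(self, rng):
        for _ in range(20):
            pm = random_pairs(rng, int(rng.integers(3, 15)))
            an = rk.two_way_anova(pm)
            est = rk.icc_agreement(an)
            assert est.ci_low <= est.icc <= est.ci_high

    def test_perfect_data_upper_bound_is_one(self):
        pm = pm_from_columns([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        _, hi = rk.icc_confidence_interval(rk.two_way_anova(pm))
        assert hi == 1.0

    def test_width_shrinks_with_n_on_average(self):
        def mean_width(n, seeds=30):
            widths = []
            for s in range(seeds):
                pm = rk.generate(
                    rk.SyntheticConfig(n_subjects=n, sigma_between=0.4,
                                       sigma_within=0.1, seed=1000 + s)
                )
                lo, hi = rk.icc_confidence_interval(rk.two_way_anova(pm))
                widths.append(hi - lo)
            return np.mean(widths)

        assert mean_width(80) < mean_width(20) < mean_width(5)

    def test_sem_is_sqrt_ms_error(self, striatum9):
        an = rk.two_way_anova(striatum9)
        assert rk.sem_from_anova(an) == pytest.approx(np.sqrt(an.ms_error))
        assert rk.sem_from_anova(an) == pytest.approx(0.0745, abs=5e-4)

    def test_sem_trivials(self):
        an = rk.AnovaDecomposition(1.0, 0.0, 0.04, 5, 2, 1.0)
        assert rk.sem_from_anova(an) == pytest.approx(0.2)
        perfect = rk.two_way_anova(pm_from_columns([1.0, 2.0], [1.0, 2.0]))
        assert rk.sem_from_anova(perfect) == 0.0
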