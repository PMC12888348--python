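import math

import numpy as np
import pandas as pd
import pytest

from bicarbkin.data_io import RunConfig, ValidationError
from bicarbkin.kinetics import KineticMetrics
from bicarbkin.reliability import (
    ICCUndefinedError,
    PairedMetric,
    classify_icc,
    coefficient_of_variation,
    icc_absolute_agreement,
    pair_metric,
    paired_comparison,
    reliability_table,
    report_for,
    typical_error,
)


def brute_force_icc21(x1, x2):
    """Independent oracle: explicit two-way ANOVA table, term by term."""
    data = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestICC:
    def test_perfect_agreement(self):
        x = [10.0, 12.0, 14.0, 16.0]
        icc, lo, hi = icc_absolute_agreement(x, x)
        assert icc == pytest.approx(1.0)

    def test_worked_four_subject_set_vs_oracle(self):
        x1, x2 = [10.0, 12.0, 14.0, 16.0], [11.0, 12.0, 13.0, 17.0]
        icc, _, _ = icc_absolute_agreement(x1, x2)
        assert icc == pytest.approx(brute_force_icc21(x1, x2), abs=1e-12)

    def test_closed_form_equals_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            x1 = rng.normal(20, 4, n)
            x2 = x1 + rng.normal(0, rng.uniform(0.1, 5), n)
            icc, _, _ = icc_absolute_agreement(x1, x2)
            assert icc == pytest.approx(brute_force_icc21(x1, x2), abs=1e-10)

    def test_matches_pingouin_point_and_interval(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 20))
            x1 = rng.normal(25, 3, n)
            x2 = x1 + rng.normal(0, 1.5, n)
            icc, lo, hi = icc_absolute_agreement(x1, x2)
            df = pd.DataFrame({
                "t": np.tile(np.arange(n), 2),
                "r": np.repeat(["a", "b"], n),
                "y": np.concatenate([x1, x2]),
            })
            row = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
            row = row[row["Type"] == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            assert lo == pytest.approx(row["CI95"][0], abs=0.01)
            assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_shuffled_pairs_average_near_zero(self):
        """Permutation oracle: independently shuffled visit 2 gives mean ICC ~ 0."""
        rng = np.random.default_rng(2)
        iccs = []
        for _ in range(1000):
            x1 = rng.normal(25, 3, 12)
            x2 = rng.permutation(rng.normal(25, 3, 12))
            iccs.append(icc_absolute_agreement(x1, x2)[0])
        assert abs(float(np.mean(iccs))) < 0.05

    def test_negative_icc_not_truncated(self):
        # anti-correlated pairs force a negative ICC
        x1 = [10.0, 12.0, 14.0, 16.0]
        x2 = [16.0, 14.0, 12.0, 10.0]
        icc, lo, _ = icc_absolute_agreement(x1, x2)
        assert icc < 0
        assert lo <= icc

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ICCUndefinedError):
            icc_absolute_agreement([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


class TestTypicalError:
    def test_identical_visits_zero(self):
        te, lo, hi = typical_error([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert te == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_value(self):
        """Differences (-1, 1, -1, 1): SD = 2/sqrt(3), TE = 0.8165."""
        x1 = [10.0, 10.0, 10.0, 10.0]
        x2 = [9.0, 11.0, 9.0, 11.0]
        te, _, _ = typical_error(x1, x2)
        assert te == pytest.approx((2 / math.sqrt(3)) / math.sqrt(2), abs=1e-4)
        assert te == pytest.approx(0.8165, abs=1e-4)

    def test_recovers_visit_noise_sd(self):
        """TE estimates the within-subject SD: mean over 500 cohorts within 5%."""
        rng = np.random.default_rng(3)
        sigma = 1.0
        tes = []
        for _ in range(500):
            mu = rng.normal(25, 2, 12)
            x1 = mu + rng.normal(0, sigma, 12)
            x2 = mu + rng.normal(0, sigma, 12)
            tes.append(typical_error(x1, x2)[0])
        assert float(np.mean(tes)) == pytest.approx(sigma, rel=0.05)

    def test_ci_brackets_point(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(25, 3, 10)
        x2 = x1 + rng.normal(0, 1, 10)
        te, lo, hi = typical_error(x1, x2)
        assert lo <= te <= hi


class TestCV:
    def test_identical_visits(self):
        cv, _, _ = coefficient_of_variation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cv == 0.0

    def test_consistency_with_te(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(25, 3, 12)
        x2 = x1 + rng.normal(0, 1, 12)
        te, _, _ = typical_error(x1, x2)
        cv, _, _ = coefficient_of_variation(x1, x2)
        grand = np.concatenate([x1, x2]).mean()
        assert cv * grand / 100.0 == pytest.approx(te, abs=1e-12)

    def test_scale_invariance(self):
        x1 = [20.0, 24.0, 28.0]
        x2 = [21.0, 23.0, 29.0]
        cv1, _, _ = coefficient_of_variation(x1, x2)
        cv2, _, _ = coefficient_of_variation([2 * v for v in x1], [2 * v for v in x2])
        assert cv1 == pytest.approx(cv2, abs=1e-12)

    def test_te_over_mean_magnitude(self):
        """TE 0.87 on a grand mean of 24.6 corresponds to CV 3.5%."""
        assert 100 * 0.87 / 24.6 == pytest.approx(3.5, abs=0.05)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([-1.0, -2.0], [-1.0, -2.0])


class TestClassifyICC:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.72, "moderate"),
            (0.23, "poor"),
            (0.90, "excellent"),
            (0.50, "moderate"),
            (0.749, "moderate"),
            (0.75, "good"),
            (0.89, "good"),
            (-0.3, "poor"),
        ],
    )
    def test_bands(self, icc, band):
        assert classify_icc(icc) == band


class TestPairedComparison:
    def test_identical_visits_degenerate(self):
        p, used = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and used == "degenerate"

    def test_detects_constant_shift_with_noise(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(25, 1, 12)
        x2 = x1 + 5.0 + rng.normal(0, 0.2, 12)
        p, used = paired_comparison(x1, x2)
        assert p < 1e-4
        assert used in ("paired-t", "wilcoxon")

    def test_type_i_error_near_alpha(self):
        """Null differences: rejection rate over 500 reps within binomial error of 5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(500):
            x1 = rng.normal(25, 2, 12)
            x2 = x1 + rng.normal(0, 1, 12)
            p, _ = paired_comparison(x1, x2)
            rejections += p <= 0.05
        rate = rejections / 500
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 500)

    def test_needs_three_pairs(self):
        with pytest.raises(ValidationError):
            paired_comparison([1.0, 2.0], [1.0, 2.0])


def _metric(subject, visit, t5, t6, baseline=24.0):
    return KineticMetrics(
        subject_id=subject, visit=visit, baseline=baseline, cmax=baseline + 9,
        ttp_min=150, time_to_delta={5.0: t5, 6.0: t6}, auc=7000.0,
    )


class TestReliabilityTable:
    def _cohort_metrics(self):
        # subject A never reaches +5; B, C, D miss +6 in at least one visit
        metrics = []
        rng = np.random.default_rng(8)
        for i, sid in enumerate("ABCDEFGHIJKL"):
            for v in (1, 2):
                if sid == "A":
                    t5 = t6 = None
                elif sid in "BCD":
                    t5, t6 = 60.0 + i + v, None
                else:
                    t5, t6 = 60.0 + i + v, 90.0 + i + 2 * v
                metrics.append(
                    _metric(sid, v, t5, t6, baseline=24.0 + rng.normal(0, 1))
                )
        return metrics

    def test_exclusion_pattern_bookkeeping(self):
        """1 subject missing +5 and 4 missing +6 -> n_pairs 11 and 8."""
        reports = {r.metric: r for r in reliability_table(self._cohort_metrics())}
        assert reports["t_plus5"].n_pairs == 11
        assert reports["t_plus5"].n_excluded == 1
        assert reports["t_plus6"].n_pairs == 8
        assert reports["t_plus6"].n_excluded == 4
        for r in reports.values():
            assert r.n_pairs + r.n_excluded == 12

    def test_all_identical_cohort(self):
        metrics = [_metric(s, v, 60.0, 90.0) for s in "ABCD" for v in (1, 2)]
        reports = reliability_table(metrics)
        for r in reports:
            assert r.te == 0.0
            assert math.isnan(r.icc)  # undefined, distinct from ICC = 1
            assert r.icc_band == "n/a"

    def test_insufficient_pairs_flagged(self):
        metrics = [_metric("A", 1, None, None), _metric("A", 2, None, None),
                   _metric("B", 1, 60.0, None), _metric("B", 2, None, None)]
        reports = {r.metric: r for r in reliability_table(metrics)}
        assert reports["t_plus5"].insufficient
        assert reports["t_plus5"].n_pairs == 0

    def test_report_interval_ordering(self):
        rng = np.random.default_rng(9)
        pairs = PairedMetric(
            "m", tuple("ABCDEFGHIJ"),
            tuple(rng.normal(25, 2, 10)), tuple(rng.normal(25, 2, 10)),
        )
        r = report_for(pairs)
        assert r.icc_ci[0] <= r.icc <= r.icc_ci[1]
        assert r.te_ci[0] <= r.te <= r.te_ci[1]
        assert r.cv_ci[0] <= r.cv_pct <= r.cv_ci[1]
        assert classify_icc(r.icc) == r.icc_band
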