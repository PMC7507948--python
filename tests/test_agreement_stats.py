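"""Agreement and diagnostic statistics against hand computations,
independent ANOVA/pair-counting oracles and coverage simulations."""
import math

import numpy as np
import pytest

from portoflow import (
    ParameterError,
    bland_altman,
    bland_altman_from_summary,
    clopper_pearson,
    diagnostic_metrics,
    group_table,
    icc_absolute_agreement,
    likelihood_ratio_ci,
    lin_ccc,
    roc_auc,
)
from portoflow.errors import UndefinedStatisticError
from portoflow.synthetic_cohort import default_group_params, generate_cohort


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([3.0, 5.0, 8.0], [3.0, 5.0, 8.0])
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_upper == 0.0 and res.loa_lower == 0.0

    def test_hand_computed_three_pairs(self):
        res = bland_altman([2.0, 3.0, 5.0], [3.0, 2.0, 5.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.loa_lower == pytest.approx(-1.96)

    def test_internal_consistency_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 60))
            x = rng.normal(10, 3, n)
            y = x + rng.normal(0.3, 1.1, n)
            res = bland_altman(x, y)
            assert res.loa_upper - res.loa_lower == pytest.approx(2 * 1.96 * res.sd_diff)
            assert 0.5 * (res.loa_upper + res.loa_lower) == pytest.approx(res.bias)
            assert res.bias_ci[0] <= res.bias <= res.bias_ci[1]
            assert res.loa_upper_ci[0] <= res.loa_upper <= res.loa_upper_ci[1]

    def test_small_or_mismatched_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bland_altman([1, 2], [1, 2])
        with pytest.raises(ParameterError):
            bland_altman([1, 2, 3], [1, 2])

    def test_bias_ci_coverage_under_normal_model(self):
        # the t interval for the mean difference is exact under normality
        rng = np.random.default_rng(12)
        n, reps, hits = 20, 600, 0
        for _ in range(reps):
            d = rng.normal(0.5, 1.0, n)
            res = bland_altman(np.zeros(n), d)
            hits += res.bias_ci[0] <= 0.5 <= res.bias_ci[1]
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(hits / reps - 0.95) <= 3 * se


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        icc, ci = icc_absolute_agreement(x, x)
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_constant_offset_penalised(self):
        x = np.linspace(5, 15, 12)
        icc, _ = icc_absolute_agreement(x, x + 8.0)
        # Pearson correlation is exactly 1 here; absolute agreement is not
        assert icc < 0.6

    def test_matches_first_principles_anova(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(10, 3, 10)
            y = x + rng.normal(0.5, 1.2, 10)
            icc, _ = icc_absolute_agreement(x, y)
            assert icc == pytest.approx(_icc_anova_oracle(x, y), rel=1e-12)

    def test_matches_pingouin_absolute_agreement(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, 10)
        y = x + rng.normal(0.5, 1.0, 10)
        icc, ci = icc_absolute_agreement(x, y)
        df = pd.DataFrame(
            {"t": list(range(10)) * 2, "r": ["a"] * 10 + ["b"] * 10,
             "s": np.concatenate([x, y])}
        )
        row = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        ref = row[row.Type == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(float(ref.ICC), abs=1e-9)
        assert ci[0] == pytest.approx(ref.CI95[0], abs=0.01)
        assert ci[1] == pytest.approx(ref.CI95[1], abs=0.01)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_absolute_agreement([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


def _icc_anova_oracle(x, y):
    """Two-way ANOVA mean squares computed with explicit loops."""
    n, k = len(x), 2
    data = [[float(x[i]), float(y[i])] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestLinCCC:
    def test_perfect_agreement(self):
        ccc, ci = lin_ccc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ccc == 1.0

    def test_hand_computed_shifted_line(self):
        ccc, _ = lin_ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert ccc == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            x = rng.normal(0, 2, n)
            y = 0.7 * x + rng.normal(1.0, 1.5, n)
            ccc, _ = lin_ccc(x, y)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_ci_coverage_bivariate_normal(self):
        rng = np.random.default_rng(9)
        # population CCC for this model, from its moment definition
        truth = 2 * 4.0 / (4.0 + 4.0 + 1.0 + 0.25)  # slope-1, var 4, noise 1, shift .5
        reps, hits = 500, 0
        for _ in range(reps):
            x = rng.normal(10, 2.0, 80)
            y = x + 0.5 + rng.normal(0, 1.0, 80)
            _, ci = lin_ccc(x, y)
            hits += ci[0] <= truth <= ci[1]
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(hits / reps - 0.95) <= 3 * se


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci = roc_auc([1, 2, 9, 10], [0, 0, 1, 1])
        assert auc == 1.0

    def test_hand_counted_case(self):
        auc, _ = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert auc == 0.75

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(scores, ~labels)
        assert a1 == pytest.approx(1.0 - a2)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestThresholdDiagnostics:
    def test_printed_two_by_two_arithmetic(self):
        lr = likelihood_ratio_ci(12, 1, 1, 11)
        assert lr.lr_pos == pytest.approx(11.1, abs=0.05)
        assert lr.lr_neg == pytest.approx(0.08, abs=0.005)

    def test_clopper_pearson_edges(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and hi < 1.0
        lo, hi = clopper_pearson(10, 10)
        assert lo > 0.0 and hi == 1.0
        with pytest.raises(ParameterError):
            clopper_pearson(5, 4)

    def test_clopper_pearson_coverage_at_least_nominal(self):
        # the exact interval is conservative: coverage >= 95%
        rng = np.random.default_rng(15)
        reps, hits, p, n = 800, 0, 0.7, 13
        for _ in range(reps):
            k = rng.binomial(n, p)
            lo, hi = clopper_pearson(int(k), n)
            hits += lo <= p <= hi
        se = math.sqrt(0.95 * 0.05 / reps)
        assert hits / reps >= 0.95 - 3 * se

    def test_symmetric_table_gives_unit_ratios(self):
        lr = likelihood_ratio_ci(5, 5, 5, 5)
        assert lr.lr_pos == pytest.approx(1.0)
        assert lr.lr_neg == pytest.approx(1.0)
        assert lr.lr_pos_ci[0] <= 1.0 <= lr.lr_pos_ci[1]
        assert lr.lr_neg_ci[0] <= 1.0 <= lr.lr_neg_ci[1]

    def test_perfect_classifier(self):
        scores = [5.0, 6.0, 20.0, 21.0]
        labels = [0, 0, 1, 1]
        rep = diagnostic_metrics(scores, labels, threshold=12.0)
        assert rep.sensitivity_pct == 100.0
        assert rep.specificity_pct == 100.0
        assert rep.lr.lr_neg == 0.0
        assert not rep.lr.lr_neg_defined

    def test_threshold_above_all_scores(self):
        rep = diagnostic_metrics([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], threshold=10.0)
        assert rep.sensitivity_pct == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            diagnostic_metrics([1.0, 2.0], [1, 1], threshold=1.5)


class TestGroupTable:
    def test_identical_groups_not_flagged(self):
        from dataclasses import replace

        g = default_group_params()[0]
        params = [replace(g, label="Control"), replace(g, label="CCl4_1mo")]
        cohort = generate_cohort(params, 50, seed=5)
        table = group_table(cohort, "fpp")
        assert not table["significant"].any()

    def test_separated_groups_flagged(self):
        cohort = generate_cohort(default_group_params(), 1000, seed=6)
        table = group_table(cohort, "fpp")
        flagged = table.set_index("group")["significant"]
        assert flagged["CCl4_4mo"]

    def test_summary_formatting(self):
        cohort = generate_cohort(default_group_params(), 200, seed=8)
        table = group_table(cohort, "diameter:portal_vein")
        control = table[table.group == "Control"].iloc[0]
        assert "±" in control["summary"]
        # one-decimal style, e.g. "4.5 ± 0.4"
        mean_str = control["summary"].split("±")[0].strip()
        assert mean_str == f"{control['mean']:.1f}"

    def test_tiny_group_rejected(self):
        cohort = generate_cohort(default_group_params(), 1, seed=0)
        with pytest.raises(ParameterError):
            group_table(cohort, "fpp")
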