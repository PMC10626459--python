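"""Prediction-error statistics, ICC from two-way ANOVA, paired t, VA summaries.

The ICC implementation is checked two independent ways: against an
explicit brute-force sums-of-squares ANOVA written with plain loops, and
against pingouin's ICC(C,1).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soiol import (
    InputValidationError,
    OutcomeRecord,
    error_band_counts,
    icc_confidence_interval,
    icc_consistency_single,
    mae,
    paired_t_test,
    prediction_errors,
    required_clinical_power,
    shapiro_normality,
    summarize_group,
    va_summary,
)


def brute_force_icc_c1(x, y):
    """Independent ICC(3,1) oracle: explicit sums of squares over the n x 2 grid."""
    n = len(x)
    k = 2
    grand = (sum(x) + sum(y)) / (n * k)
    row_means = [(a + b) / 2 for a, b in zip(x, y)]
    col_means = [sum(x) / n, sum(y) / n]
    ss_rows = sum(k * (m - grand) ** 2 for m in row_means)
    ss_total = sum((v - grand) ** 2 for v in list(x) + list(y))
    ss_cols = sum(n * (m - grand) ** 2 for m in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def test_required_clinical_power_examples():
    assert required_clinical_power(26, -7.0) == 19.0
    assert required_clinical_power(18, +8.0) == 26.0
    assert required_clinical_power(21.5, 0.0) == 21.5
    with pytest.raises(InputValidationError):
        required_clinical_power(float("nan"), 0.0)


def _rec(pid, theo, impl, sph, k=43.0, **va):
    return OutcomeRecord(pid, theo, impl, sph, k, **va)


def test_prediction_errors_rows(group_a_outcomes):
    table = prediction_errors(group_a_outcomes)
    assert len(table) == 13
    by_id = dict(zip(table.patient_ids, table.abs_error_d))
    assert by_id["A01"] == pytest.approx(6.23, abs=1e-9)
    assert by_id["A04"] == pytest.approx(6.16, abs=1e-9)
    assert by_id["A03"] == pytest.approx(0.05, abs=1e-9)  # |21.7 - 21.75|
    assert all(
        a == abs(s) for a, s in zip(table.abs_error_d, table.signed_error_d)
    )


def test_prediction_errors_empty():
    with pytest.raises(InputValidationError):
        prediction_errors([])


def test_mae_zero_for_perfect_predictions():
    recs = [_rec(f"p{i}", 20.0, 20.0, 0.0) for i in range(4)]
    assert mae(prediction_errors(recs)) == (0.0, 0.0)
    with pytest.raises(InputValidationError):
        mae(prediction_errors(recs[:1]))


def test_error_band_half_open_convention():
    recs = [_rec("a", 21.5, 20.0, 0.0)]  # abs error exactly 1.5
    assert error_band_counts(prediction_errors(recs)) == (0, 0, 0, 1, 0)
    recs2 = [_rec("b", 20.499999, 20.0, 0.0)]
    assert error_band_counts(prediction_errors(recs2)) == (1, 0, 0, 0, 0)


def test_band_counts_and_mae_permutation_invariant(group_a_outcomes):
    table = prediction_errors(group_a_outcomes)
    rng = np.random.default_rng(7)
    shuffled = list(group_a_outcomes)
    rng.shuffle(shuffled)
    table2 = prediction_errors(shuffled)
    assert error_band_counts(table) == error_band_counts(table2)
    assert mae(table) == pytest.approx(mae(table2))
    assert sum(error_band_counts(table)) == len(table)


def test_icc_perfect_and_shift_invariance():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert icc_consistency_single(x, x).icc == pytest.approx(1.0)
    shifted = [v + 2.5 for v in x]
    assert icc_consistency_single(x, shifted).icc == pytest.approx(1.0)


def test_icc_strictly_below_one_with_residual_noise():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = x + rng.normal(scale=0.3, size=20)
    res = icc_consistency_single(x, y)
    assert res.icc < 1.0


def test_icc_degenerate_flagged():
    with pytest.warns(UserWarning, match="degenerate"):
        res = icc_consistency_single([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.degenerate and math.isnan(res.icc)


def test_icc_matches_brute_force_oracle_on_random_data():
    rng = np.random.default_rng(42)
    for _ in range(500):
        n = int(rng.integers(3, 25))
        x = rng.normal(rng.uniform(-5, 25), rng.uniform(0.5, 5), size=n)
        y = x + rng.normal(0, rng.uniform(0.1, 3), size=n)
        got = icc_consistency_single(x, y).icc
        assert got == pytest.approx(brute_force_icc_c1(list(x), list(y)), abs=1e-10)


def test_icc_matches_pingouin(group_a_outcomes):
    import pandas as pd
    import pingouin as pg

    table = prediction_errors(group_a_outcomes)
    res = icc_consistency_single(table.theoretical_d, table.clinical_required_d)
    lo, hi = icc_confidence_interval(res)
    df = pd.DataFrame(
        {
            "subject": list(range(13)) * 2,
            "rater": ["theory"] * 13 + ["clinic"] * 13,
            "score": list(table.theoretical_d) + list(table.clinical_required_d),
        }
    )
    pg_row = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type").loc["ICC(C,1)"]
    assert res.icc == pytest.approx(float(pg_row["ICC"]), abs=1e-9)
    assert (round(lo, 2), round(hi, 2)) == tuple(np.round(pg_row["CI95"], 2))


def test_icc_ci_behavior():
    rng = np.random.default_rng(3)
    x = rng.normal(size=15)
    res = icc_consistency_single(x, x + rng.normal(scale=0.05, size=15))
    lo, hi = icc_confidence_interval(res)
    assert lo <= res.icc <= hi
    assert lo > 0.8  # near-perfect agreement keeps the whole CI high
    # alpha -> 1 collapses the interval toward the point estimate.
    lo9, hi9 = icc_confidence_interval(res, alpha=0.9)
    assert hi9 - lo9 < hi - lo
    with pytest.raises(InputValidationError):
        icc_confidence_interval(res, alpha=1.5)


def test_paired_t_basics():
    x = [1.0, 2.0, 3.0, 4.0]
    with pytest.warns(UserWarning):
        t, p = paired_t_test(x, x)
    assert t == 0.0 and math.isnan(p)
    t2, _ = paired_t_test([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])
    assert t2 == pytest.approx(0.0)  # balanced +/- differences


def test_paired_t_matches_sign_permutation_reference():
    """Two-sided t p-value vs a 200k-draw random sign-flip reference."""
    rng = np.random.default_rng(11)
    x = rng.normal(0.0, 1.0, size=12)
    y = x + rng.normal(0.4, 1.0, size=12)
    t_obs, p_t = paired_t_test(x, y)
    d = x - y
    signs = rng.choice([-1.0, 1.0], size=(200_000, d.size))
    flipped = signs * d
    t_null = flipped.mean(1) / (flipped.std(1, ddof=1) / np.sqrt(d.size))
    p_perm = float(np.mean(np.abs(t_null) >= abs(t_obs)))
    assert abs(p_t - p_perm) < 0.01


def test_shapiro_advisory(group_a_outcomes):
    table = prediction_errors(group_a_outcomes)
    w, p = shapiro_normality(table.theoretical_d)
    assert 0.0 < w <= 1.0 and 0.0 <= p <= 1.0


def test_summarize_group_composes(group_a_outcomes):
    report = summarize_group(group_a_outcomes)
    assert report.n == 13
    assert sum(report.band_counts) == report.n
    assert report.icc_ci_low <= report.icc <= report.icc_ci_high
    assert min(report.sd_theoretical, report.sd_clinical, report.sd_abs_error) >= 0
    # serialization round-trips through JSON
    import json

    loaded = json.loads(report.to_json())
    assert loaded["n"] == 13 and loaded["mae"] == pytest.approx(report.mae)
    assert report.to_tsv().count("\n") == 2


def test_summarize_group_degenerate_duplicates():
    recs = [_rec(f"p{i}", 20.0, 19.0, 1.0) for i in range(5)]
    with pytest.warns(UserWarning):
        report = summarize_group(recs)
    assert math.isnan(report.icc)
    assert any("degenerate" in n for n in report.notes)


def test_va_summary_constant_column_and_pairwise_exclusion():
    recs = [
        _rec("a", 20, 20, 0, va_preop_uncorrected=1.0, va_preop_corrected=0.8,
             va_postop_corrected=0.5),
        _rec("b", 20, 20, 0, va_preop_uncorrected=1.0, va_preop_corrected=0.9,
             va_postop_corrected=0.6),
        _rec("c", 20, 20, 0, va_preop_uncorrected=1.0, va_preop_corrected=None,
             va_postop_corrected=0.7),
    ]
    with pytest.warns(UserWarning, match="excluded pairwise"):
        s = va_summary(recs)
    assert s.preop_uncorrected == (1.0, 0.0)  # constant column has zero SD
    assert s.n == 3


def test_va_summary_requires_some_columns():
    with pytest.raises(InputValidationError):
        va_summary([_rec("a", 20, 20, 0), _rec("b", 20, 20, 0)])


@given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
@settings(max_examples=50, deadline=None)
def test_icc_column_shift_invariance_property(deltas):
    """Adding a common constant to one column never changes consistency ICC."""
    x = np.arange(len(deltas), dtype=float)
    y = x + np.asarray(deltas)
    base = icc_consistency_single(x, y)
    shifted = icc_consistency_single(x, y + 3.7)
    if not base.degenerate:
        assert shifted.icc == pytest.approx(base.icc, abs=1e-9)
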