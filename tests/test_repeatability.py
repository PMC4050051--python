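import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import anova_mean_squares, icc_a1, pearson_r
from choroseg.repeatability import (RepeatedMeasures, bland_altman,
                                    build_report,
                                    coefficient_of_repeatability,
                                    icc_absolute, paired_diff, rm_anova)


def test_paired_diff_zero_for_identical_sessions():
    a = np.array([100.0, 120.0, 140.0, 90.0])
    mean, ci, loa = paired_diff(a, a)
    assert mean == 0 and loa == (0, 0) and ci == (0, 0)


def test_paired_diff_two_sd_rule():
    a = np.array([1.0, 2.0, 3.0])
    b = np.zeros(3)
    mean, ci, loa = paired_diff(a, b)
    assert mean == pytest.approx(2.0)
    assert loa == (pytest.approx(0.0), pytest.approx(4.0))   # mean +- 2 SD


def test_paired_diff_ci_matches_t_quantile():
    # d = [1, 2, 3]: CI = 2 +- t_{0.975,2} / sqrt(3), t_{0.975,2} = 4.3027
    mean, ci, _ = paired_diff(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    t = stats.t.ppf(0.975, 2)
    assert t == pytest.approx(4.30265, abs=1e-5)
    assert ci[0] == pytest.approx(2 - t / np.sqrt(3), abs=1e-12)
    assert ci[1] == pytest.approx(2 + t / np.sqrt(3), abs=1e-12)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40),
       st.floats(-100, 100))
def test_loa_width_is_exactly_four_sd(diffs, offset):
    d = np.asarray(diffs)
    a = d + offset
    b = np.full_like(d, offset)
    _, _, loa = paired_diff(a, b)
    assert loa[1] - loa[0] == pytest.approx(4 * np.std(d, ddof=1), abs=1e-9)


def test_bland_altman_flags_constant_offset():
    a = np.array([5.0, 5.0, 5.0, 5.0])
    out = bland_altman(a + 3, a)
    assert out["flag"] == "zero-variance"
    assert np.isnan(out["r"])


def test_bland_altman_detects_proportional_bias():
    a = np.linspace(50, 300, 12)
    out = bland_altman(a, 0.5 * a)
    assert out["r"] > 0.999 and out["p"] < 1e-6


def test_bland_altman_matches_brute_force_correlation():
    rng = np.random.default_rng(4)
    a = rng.uniform(80, 250, 10)
    b = a + rng.normal(0, 8, 10)
    out = bland_altman(a, b)
    assert out["r"] == pytest.approx(pearson_r(a - b, (a + b) / 2),
                                     abs=1e-12)


def test_icc_identical_columns_is_one():
    x = np.column_stack([np.array([1.0, 5.0, 9.0, 2.0])] * 3)
    icc, _ = icc_absolute(RepeatedMeasures(x))
    assert icc == pytest.approx(1.0)


def test_icc_near_zero_under_the_null():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(500, 3))           # no subject effect at all
    icc, _ = icc_absolute(RepeatedMeasures(x))
    assert abs(icc) <= 0.1


def test_icc_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(7)
    x = rng.uniform(50, 250, size=(5, 2))
    icc, _ = icc_absolute(RepeatedMeasures(x))
    assert icc == pytest.approx(icc_a1(x), abs=1e-9)


def test_icc_matches_pingouin_absolute_agreement():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    subject_effect = rng.normal(0, 40, 8)
    x = subject_effect[:, None] + rng.normal(0, 10, (8, 3))
    icc, ci = icc_absolute(RepeatedMeasures(x))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(8), 3),
        "rater": np.tile(np.arange(3), 8),
        "value": x.ravel()})
    ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="value").set_index("Type")
    assert icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
    np.testing.assert_allclose(ci, ref.loc["ICC(A,1)", "CI95"], atol=6e-3)


def test_icc_invariant_under_affine_rescaling():
    rng = np.random.default_rng(2)
    x = rng.uniform(50, 250, size=(7, 3))
    icc, _ = icc_absolute(RepeatedMeasures(x))
    icc2, _ = icc_absolute(RepeatedMeasures(3.7 * x + 11.0))
    assert icc2 == pytest.approx(icc, abs=1e-12)


def test_icc_undefined_for_zero_variance():
    icc, ci = icc_absolute(RepeatedMeasures(np.full((4, 2), 7.0)))
    assert np.isnan(icc) and np.isnan(ci[0])


def test_cr_formula_and_degenerate_cases():
    d = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0], ddof=1)
    cr_abs, cr_pct = coefficient_of_repeatability(d, 100.0)
    assert cr_abs == pytest.approx(1.96)
    assert cr_pct == pytest.approx(1.96)
    cr0, pct0 = coefficient_of_repeatability(np.zeros(5), 10.0)
    assert cr0 == 0.0 and pct0 == 0.0
    _, undef = coefficient_of_repeatability(np.ones(3), 0.0)
    assert np.isnan(undef)


def test_cr_matches_independent_formula():
    rng = np.random.default_rng(3)
    a = rng.uniform(80, 250, 10)
    b = a + rng.normal(0, 5, 10)
    cr_abs, cr_pct = coefficient_of_repeatability(a - b,
                                                  np.mean(np.r_[a, b]))
    sd = np.sqrt(np.sum((a - b - (a - b).mean()) ** 2) / 9)
    assert cr_abs == pytest.approx(1.96 * sd, abs=1e-12)
    assert cr_pct == pytest.approx(100 * 1.96 * sd / np.mean(np.r_[a, b]),
                                   abs=1e-12)


def test_rm_anova_degenerate_and_strong_effect():
    x = np.tile(np.array([[1.0], [5.0], [9.0]]), (1, 3))
    f, p = rm_anova(RepeatedMeasures(x))
    assert f == 0.0 and p == 1.0
    rng = np.random.default_rng(5)
    base = rng.normal(100, 10, 8)
    shifted = np.column_stack([base, base + 100 * 10])
    _, p2 = rm_anova(RepeatedMeasures(shifted))
    assert p2 < 0.001


def test_rm_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(9)
    x = rng.uniform(50, 250, size=(6, 3))
    f, p = rm_anova(RepeatedMeasures(x))
    msr, msc, mse = anova_mean_squares(x)
    assert f == pytest.approx(msc / mse, abs=1e-9)
    assert p == pytest.approx(stats.f.sf(msc / mse, 2, 10), abs=1e-12)


def test_rm_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(13)
    x = rng.uniform(50, 250, size=(6, 3))
    f, p = rm_anova(RepeatedMeasures(x))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(6), 3),
        "session": np.tile(np.arange(3), 6),
        "value": x.ravel()})
    ref = pingouin.rm_anova(data=long, dv="value", within="session",
                            subject="subject")
    assert f == pytest.approx(ref["F"].iloc[0], abs=1e-9)
    assert p == pytest.approx(ref["p_unc"].iloc[0], abs=1e-9)


def _long_format(values_by_layer_field, n_sessions):
    rows = []
    for (layer, field), mat in values_by_layer_field.items():
        n = mat.shape[0]
        for s in range(n_sessions):
            for i in range(n):
                rows.append({"subject": i, "session": s + 1, "layer": layer,
                             "field": field, "value": mat[i, s]})
    return pd.DataFrame(rows)


def test_report_identical_sessions_gives_perfect_agreement():
    base = np.array([100.0, 150.0, 200.0, 120.0, 90.0])
    mat = np.column_stack([base] * 3)
    data = _long_format({("haller", "csm"): mat, ("sattler", "csm"): mat},
                        3)
    report = build_report(data)
    assert (report.delta == 0).all()
    assert (report.icc == 1).all()
    assert (report.cr_abs == 0).all()


def test_report_shape_and_composition_consistency():
    rng = np.random.default_rng(21)
    mats = {}
    for layer in ("sattler", "haller"):
        for field in ("csm", "total"):
            base = rng.uniform(80, 250, 10)
            mats[(layer, field)] = base[:, None] + rng.normal(0, 6, (10, 3))
    report = build_report(_long_format(mats, 3))
    assert len(report) == 2 * 2 * 2                # layers x fields x pairs
    row = report[(report.layer == "haller") & (report.field == "csm")
                 & (report.comparison == "R1-R2")].iloc[0]
    a = mats[("haller", "csm")][:, 0]
    b = mats[("haller", "csm")][:, 1]
    mean, ci, loa = paired_diff(a, b)
    assert row.delta == pytest.approx(mean)
    assert (row.loa_low, row.loa_high) == (pytest.approx(loa[0]),
                                           pytest.approx(loa[1]))
    icc, _ = icc_absolute(RepeatedMeasures(np.column_stack([a, b])))
    assert row.icc == pytest.approx(icc)
    cr_abs, cr_pct = coefficient_of_repeatability(
        a - b, float(np.mean(np.concatenate([a, b]))))
    assert row.cr_abs == pytest.approx(cr_abs)
    assert row.cr_pct == pytest.approx(cr_pct)


def test_report_rejects_inconsistent_subjects():
    data = _long_format({("haller", "csm"): np.ones((4, 3))}, 3)
    data = data.drop(data[(data.subject == 2) & (data.session == 3)].index)
    with pytest.raises(ValueError, match="inconsistent"):
        build_report(data)


def test_repeated_measures_validation():
    with pytest.raises(ValueError):
        RepeatedMeasures(np.ones((1, 3)))
    bad = np.ones((4, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        RepeatedMeasures(bad)
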