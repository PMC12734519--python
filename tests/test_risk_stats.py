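"""Statistical battery: 2x2 dichotomisation, odds ratios, corrected
chi-square, Mann-Whitney / Hodges-Lehmann, t test and normality routing.

Independent oracles: statsmodels logistic regression for the odds ratio,
scipy for chi-square and t, and exhaustive permutation enumeration for the
Mann-Whitney normal approximation.
"""

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats as sps

import pdrscreen as p

FACTORS = {f.name: f for f in p.BUILTIN_FACTORS}


def _single_record(group=p.Group.PDR, control=p.Control.POOR):
    return p.PatientRecord(
        patient_id="x", group=group, sex=p.Sex.FEMALE, age_years=40,
        onset_age_years=20, duration_years=20, hba1c_current_pct=8.0,
        fasting_glucose_mmol_l=7.0, sbp_mmhg=130, dbp_mmhg=80,
        total_chol_mmol_l=4.0, ldl_mmol_l=2.0, tg_mmol_l=1.5,
        longterm_control=control, exam_regularity=p.ExamRegularity.REGULAR)


def _duration_cohort(durations_pdr, durations_npdr):
    out = []
    for g, durs in ((p.Group.PDR, durations_pdr), (p.Group.NPDR, durations_npdr)):
        for i, d in enumerate(durs):
            rec = _single_record(group=g)
            rec.patient_id = f"{g.value}-{i}"
            rec.duration_years = d
            rec.age_years = rec.onset_age_years + d
            out.append(rec)
    return out


# -- dichotomize -------------------------------------------------------------


def test_dichotomize_single_record_cohort():
    t = p.dichotomize([_single_record()], FACTORS["longterm_control"])
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)


def test_dichotomize_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty"):
        p.dichotomize([], FACTORS["onset_age"])


def test_duration_split_uses_cohort_median_and_flags_ties():
    cohort = _duration_cohort([10, 20, 30], [10, 20, 30])
    with pytest.raises(p.ThresholdTieError) as exc:
        p.dichotomize(cohort, FACTORS["duration"])
    assert len(exc.value.ids) == 2  # the two records at the median 20
    t = p.dichotomize(cohort, FACTORS["duration"], tie_policy="lower")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 2)  # > 20 vs <= 20
    t_up = p.dichotomize(cohort, FACTORS["duration"], tie_policy="upper")
    assert (t_up.a, t_up.b, t_up.c, t_up.d) == (2, 2, 1, 1)


def test_explicit_threshold_overrides_median():
    cohort = _duration_cohort([10, 30], [10, 30])
    from dataclasses import replace
    factor = replace(FACTORS["duration"], threshold=25.0)
    t = p.dichotomize(cohort, factor)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_counts_always_sum_to_cohort_size(study_cohort):
    for factor in p.BUILTIN_FACTORS:
        t = p.dichotomize(study_cohort, factor)
        assert t.total == len(study_cohort)


# -- odds ratio --------------------------------------------------------------


@pytest.mark.parametrize("cells, or_expected, ci_expected", [
    ((23, 9, 4, 22), 506 / 36, (3.774, 52.35)),
    ((22, 4, 5, 27), 29.7, (7.106, 124.14)),
    ((16, 4, 11, 27), 432 / 44, (2.674, 36.05)),
    ((20, 9, 7, 22), 440 / 63, (2.193, 22.25)),
])
def test_odds_ratio_point_and_woolf_ci(cells, or_expected, ci_expected):
    r = p.odds_ratio(p.ContingencyTable2x2(*cells))
    assert r.or_point == pytest.approx(or_expected, rel=1e-12)
    assert r.ci_low == pytest.approx(ci_expected[0], abs=5e-3)
    assert r.ci_high == pytest.approx(ci_expected[1], abs=5e-2)
    assert not r.continuity_adjusted
    assert r.p_value < 0.01


def test_uniform_table_gives_unit_or_straddled_by_ci():
    r = p.odds_ratio(p.ContingencyTable2x2(5, 5, 5, 5))
    assert r.or_point == 1.0
    assert r.ci_low < 1.0 < r.ci_high
    assert r.p_value == pytest.approx(1.0)


def test_haldane_adjustment_on_single_zero_cell():
    # (1,0,1,1) + 0.5 everywhere: OR = (1.5*1.5)/(0.5*1.5) = 3
    r = p.odds_ratio(p.ContingencyTable2x2(1, 0, 1, 1))
    assert r.continuity_adjusted
    assert r.or_point == pytest.approx(3.0)


def test_double_zero_diagonal_is_undefined():
    with pytest.raises(ValueError, match="diagonal"):
        p.odds_ratio(p.ContingencyTable2x2(0, 1, 1, 0))
    with pytest.raises(ValueError, match="diagonal"):
        p.odds_ratio(p.ContingencyTable2x2(1, 0, 0, 1))


@pytest.mark.parametrize("cells", [(23, 9, 4, 22), (5, 7, 11, 3), (40, 12, 9, 33)])
def test_or_matches_logistic_regression_oracle(cells):
    """exp(slope) of a univariate binary-exposure logit equals the
    cross-product ratio, to 6 significant figures."""
    a, b, c, d = cells
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    ours = p.odds_ratio(p.ContingencyTable2x2(*cells)).or_point
    assert ours == pytest.approx(math.exp(fit.params[1]), rel=1e-6)


@given(st.tuples(*[st.integers(1, 30)] * 4), st.integers(2, 6))
def test_or_invariant_under_row_and_column_scaling(cells, k):
    base = p.odds_ratio(p.ContingencyTable2x2(*cells)).or_point
    a, b, c, d = cells
    row = p.odds_ratio(p.ContingencyTable2x2(k * a, k * b, c, d)).or_point
    col = p.odds_ratio(p.ContingencyTable2x2(k * a, b, k * c, d)).or_point
    assert row == pytest.approx(base, rel=1e-12)
    assert col == pytest.approx(base, rel=1e-12)


def test_woolf_ci_coverage_on_simulated_tables():
    """95% Woolf intervals cover a known odds ratio in 93-97% of 1000
    binomial 2x2 draws."""
    rng = np.random.default_rng(7)
    p1, p2, n = 0.6, 0.3, 50
    true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
    cover = 0
    for _ in range(1000):
        a, b = int(rng.binomial(n, p1)), int(rng.binomial(n, p2))
        r = p.odds_ratio(p.ContingencyTable2x2(a, b, n - a, n - b))
        cover += r.ci_low <= true_or <= r.ci_high
    assert 930 <= cover <= 970


# -- chi-square --------------------------------------------------------------


@pytest.mark.parametrize("cells, printed", [
    ((23, 9, 4, 22), 16.2),
    ((22, 4, 5, 27), 24.7),
    ((16, 4, 11, 27), 11.7),
    ((20, 9, 7, 22), 9.9),
])
def test_yates_chi_square_reproduces_intext_values(cells, printed):
    r = p.chi_square_corrected(p.ContingencyTable2x2(*cells))
    assert r.df == 1
    assert abs(r.statistic - printed) <= 0.1
    assert r.p_value < 0.01


def test_pearson_exceeds_yates_and_pins_the_correction():
    t = p.ContingencyTable2x2(23, 9, 4, 22)
    pearson = p.chi_square_corrected(t, correction=False).statistic
    yates = p.chi_square_corrected(t).statistic
    assert pearson == pytest.approx(18.4, abs=0.05)  # would NOT print as 16.2
    assert yates < pearson


def test_proportional_table_clamps_to_zero():
    r = p.chi_square_corrected(p.ContingencyTable2x2(10, 20, 5, 10))
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        p.chi_square_corrected(p.ContingencyTable2x2(0, 0, 5, 5))


@pytest.mark.parametrize("cells", [(23, 9, 4, 22), (12, 7, 9, 30), (3, 14, 18, 2)])
def test_chi_square_matches_scipy_oracle(cells):
    obs = np.array(cells).reshape(2, 2)
    for corr in (True, False):
        ours = p.chi_square_corrected(p.ContingencyTable2x2(*cells), correction=corr)
        ref = sps.chi2_contingency(obs, correction=corr)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


@given(st.tuples(*[st.integers(1, 40)] * 4))
def test_chi_square_symmetry_and_correction_inequality(cells):
    a, b, c, d = cells
    t = p.ContingencyTable2x2(a, b, c, d)
    swapped = p.ContingencyTable2x2(d, c, b, a)  # rows and columns swapped
    assert (p.chi_square_corrected(t).statistic
            == pytest.approx(p.chi_square_corrected(swapped).statistic, rel=1e-12))
    assert (p.chi_square_corrected(t).statistic
            <= p.chi_square_corrected(t, correction=False).statistic + 1e-12)


# -- Mann-Whitney / Hodges-Lehmann ------------------------------------------


def test_identical_samples_give_zero_shift_and_z():
    est = p.mann_whitney_shift([1, 2, 3], [1, 2, 3])
    assert est.hl_shift == 0.0
    assert est.z == 0.0
    assert est.p_value == 1.0


def test_pure_location_shift_recovered():
    est = p.mann_whitney_shift([11, 12, 13], [1, 2, 3])
    assert est.hl_shift == 10.0
    assert est.ci_low <= est.hl_shift <= est.ci_high


def test_all_tied_samples_degenerate_but_finite():
    est = p.mann_whitney_shift([5, 5], [5, 5, 5])
    assert est.hl_shift == est.ci_low == est.ci_high == 0.0
    assert est.p_value == 1.0


def test_empty_sample_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        p.mann_whitney_shift([], [1.0])


def _exact_two_sided_p(pooled, n):
    """Permutation null of U over all label assignments (combined n <= 8)."""
    pooled = np.asarray(pooled, dtype=float)
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    mu = n * (big_n - n) / 2
    obs_u = ranks[:n].sum() - n * (n + 1) / 2
    devs = []
    for idx in itertools.combinations(range(big_n), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        devs.append(abs(u - mu))
    devs = np.array(devs)
    return float((devs >= abs(obs_u - mu) - 1e-12).mean())


@pytest.mark.parametrize("big_n", [6, 7, 8])
def test_normal_approximation_close_to_exact_enumeration(big_n):
    """Two-sided normal-approximation p within 0.05 of the exact
    permutation p, exhaustively over every partition of distinct pooled
    values (the approximation's stated accuracy regime; with N <= 5 or
    heavy ties the permutation null is too lumpy for that bound)."""
    pooled = np.arange(1.0, big_n + 1)
    for n in range(2, big_n - 1):
        for idx in itertools.combinations(range(big_n), n):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            est = p.mann_whitney_shift(x, y)
            exact = _exact_two_sided_p(np.r_[x, y], n)
            assert abs(est.p_value - exact) <= 0.05, (big_n, n, idx)


@pytest.mark.parametrize("seed", range(8))
def test_normal_approximation_sane_under_ties(seed):
    """With coarse tied data at tiny n the lumpy permutation null allows
    larger gaps; the approximation still stays within 0.2 and on [0, 1]."""
    rng = np.random.default_rng(seed)
    big_n = int(rng.integers(5, 9))
    n = int(rng.integers(2, big_n - 1))
    pooled = rng.integers(0, 5, size=big_n).astype(float)
    if np.ptp(pooled) == 0:
        pooled[0] += 1
    est = p.mann_whitney_shift(pooled[:n], pooled[n:])
    exact = _exact_two_sided_p(pooled, n)
    assert abs(est.p_value - exact) <= 0.2
    assert 0 <= est.p_value <= 1


@given(st.lists(st.integers(0, 20), min_size=2, max_size=10),
       st.lists(st.integers(0, 20), min_size=2, max_size=10))
def test_shift_ci_brackets_estimate_and_u_in_range(xs, ys):
    est = p.mann_whitney_shift(xs, ys)
    assert est.ci_low <= est.hl_shift <= est.ci_high
    assert 0 <= est.u_statistic <= len(xs) * len(ys)
    assert 0 <= est.p_value <= 1


# -- t test ------------------------------------------------------------------


def test_t_equal_samples():
    stat, pv = p.t_test([1, 2, 3], [1, 2, 3])
    assert stat == 0.0
    assert pv == pytest.approx(1.0)


def test_t_hand_arithmetic_and_scipy_oracle():
    # x={0,2}, y={1,3}: pooled variance 2, se = sqrt(2), t = -1/sqrt(2)
    stat, pv = p.t_test([0, 2], [1, 3])
    assert stat == pytest.approx(-1 / math.sqrt(2))
    ref = sps.ttest_ind([0, 2], [1, 3], equal_var=True)
    assert stat == pytest.approx(ref.statistic, rel=1e-12)
    assert pv == pytest.approx(ref.pvalue, rel=1e-12)


def test_t_antisymmetric_in_sample_order():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    s1, p1 = p.t_test(x, y)
    s2, p2 = p.t_test(y, x)
    assert s1 == pytest.approx(-s2)
    assert p1 == pytest.approx(p2)


def test_t_degenerate_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        p.t_test([1, 1], [1, 1])


# -- normality routing -------------------------------------------------------


def test_uniform_samples_route_non_normal():
    hits = 0
    for seed in range(100):
        x = np.random.default_rng(seed).uniform(0, 1, 200)
        hits += p.normality_route(x) is p.Normality.NON_NORMAL
    assert hits >= 95


def test_normal_samples_mostly_route_normal():
    hits = 0
    for seed in range(100):
        x = np.random.default_rng(seed).normal(0, 1, 200)
        hits += p.normality_route(x) is p.Normality.NORMAL
    assert 88 <= hits <= 100  # ~95% minus alpha-level rejections


def test_degenerate_spread_routes_without_crash():
    x = np.full(50, 3.0)
    assert p.normality_route(x) is p.Normality.NON_NORMAL
    x_noise = 3.0 + 1e-12 * np.arange(50)
    assert p.normality_route(x_noise) in (p.Normality.NORMAL, p.Normality.NON_NORMAL)


def test_small_sample_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        p.normality_route([1.0, 2.0, 3.0])


# -- whole-cohort comparison -------------------------------------------------


def test_compare_groups_reproduces_published_factor_table(study_cohort):
    rows, blocks = p.compare_groups(study_cohort)
    ors = [orr.or_point for _, _, orr, _ in blocks]
    chis = [chi.statistic for _, _, _, chi in blocks]
    assert ors == pytest.approx([14, 29.7, 9.8, 7], rel=0.01)
    for got, printed in zip(chis, [16.2, 24.7, 11.7, 9.9]):
        assert abs(got - printed) <= 0.1
    assert len(rows) == len(p.TABLE1_CONTINUOUS) + len(p.TABLE1_CATEGORICAL)


def test_compare_groups_requires_both_groups(study_cohort):
    only_pdr = [r for r in study_cohort if r.group is p.Group.PDR]
    with pytest.raises(ValueError, match="both"):
        p.compare_groups(only_pdr)


def test_compare_groups_summary_style_matches_test_family(study_cohort):
    rows, _ = p.compare_groups(study_cohort)
    for row in rows:
        if row.test == "mann_whitney":
            assert "[" in row.pdr_summary  # median [min-max] form
        elif row.test == "t_test":
            assert "+/-" in row.pdr_summary  # mean +/- SD form


def test_compare_groups_on_synthetic_cohort_recovers_spec():
    spec = p.CohortSpec.default(scale=40)
    cohort = p.generate_cohort(spec, 99)
    rows, blocks = p.compare_groups(cohort)
    # duration factor splits at the cohort median; counts cover everyone
    for _, tab, orr, chi in blocks:
        assert tab.total == len(cohort)
        assert 0 <= orr.p_value <= 1 and 0 <= chi.p_value <= 1
    t2 = p.table2_frame(blocks)
    assert list(t2["factor"]) == [f.name for f in p.BUILTIN_FACTORS]
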