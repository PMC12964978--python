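"""Effect measures, matched-pair tests, KM/log-rank/Cox and sample size."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pneumocea import outcomes
from pneumocea.exceptions import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    EmptyInputError,
)
from conftest import cox_partial_loglik, empirical_survivor


# --- effect measures -------------------------------------------------------


def test_matched_cohort_effect_measures():
    """4/33 vs 16/33 recurrences: 12.1% vs 48.5%, ARR 36.4%, NNT 2.75."""
    eff = outcomes.effect_summary(outcomes.TwoByTwo(4, 33, 16, 33))
    pres = eff.as_presentation()
    assert pres["rate_treated_pct"] == 12.1
    assert pres["rate_control_pct"] == 48.5
    assert pres["arr_pct"] == 36.4
    assert pres["nnt"] == 2.75
    assert eff.nnt == pytest.approx(33 / 12)


def test_zero_arr_gives_undefined_nnt():
    eff = outcomes.effect_summary(outcomes.TwoByTwo(5, 10, 5, 10))
    assert eff.arr == 0.0
    assert math.isinf(eff.nnt)
    assert "undefined" in eff.nnt_note


def test_extreme_two_by_two():
    eff = outcomes.effect_summary(outcomes.TwoByTwo(0, 10, 10, 10))
    assert eff.arr == 1.0
    assert eff.nnt == 1.0
    assert eff.rr == 0.0


@settings(max_examples=50, derandomize=True)
@given(
    a=st.integers(0, 50), na=st.integers(1, 50), b=st.integers(0, 50), nb=st.integers(1, 50)
)
def test_effect_identities_hold_in_rational_arithmetic(a, na, b, nb):
    a, b = min(a, na), min(b, nb)
    eff = outcomes.effect_summary(outcomes.TwoByTwo(a, na, b, nb))
    arr = Fraction(b, nb) - Fraction(a, na)
    assert eff.arr == pytest.approx(float(arr), abs=1e-15)
    if arr > 0:
        assert Fraction(eff.nnt).limit_denominator(10**6) * arr == 1


# --- McNemar ---------------------------------------------------------------


def test_mcnemar_exact_symmetric_is_capped_at_one():
    assert outcomes.mcnemar_test(5, 5).p_value == 1.0


def test_mcnemar_exact_binomial_tail_values():
    # 2 * sum_{k<=2} C(16,k) / 2^16
    expected = 2 * sum(math.comb(16, k) for k in range(3)) / 2**16
    assert outcomes.mcnemar_test(14, 2).p_value == pytest.approx(expected, rel=1e-12)
    assert outcomes.mcnemar_test(12, 0).p_value == pytest.approx(2 / 4096, rel=1e-12)


def test_mcnemar_degenerate_no_discordance():
    res = outcomes.mcnemar_test(0, 0)
    assert res.p_value == 1.0 and res.degenerate


def test_mcnemar_exact_approaches_chi_square_with_size():
    gaps = []
    for n in (10, 100, 1000):
        b, c = int(0.6 * n), int(0.4 * n)
        ex = outcomes.mcnemar_test(b, c, "exact").p_value
        ch = outcomes.mcnemar_test(b, c, "chi_square").p_value
        gaps.append(abs(ex - ch))
    assert gaps[0] > gaps[1] > gaps[2]


# --- Kaplan–Meier ----------------------------------------------------------


def test_km_no_censoring_equals_empirical_survivor():
    fit = outcomes.km_fit([1, 2, 3, 4], [1, 1, 1, 1])
    for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
        assert outcomes.survival_at(fit, t) == pytest.approx(s)


def test_km_product_limit_with_censoring():
    fit = outcomes.km_fit([1, 2, 3, 4], [1, 0, 1, 0])
    assert outcomes.survival_at(fit, 1) == pytest.approx(0.75)
    assert outcomes.survival_at(fit, 3) == pytest.approx(0.375)


def test_km_few_events_median_not_reached():
    times = [60.0] * 29 + [5.0, 12.0, 30.0, 44.0]
    events = [0] * 29 + [1] * 4
    fit = outcomes.km_fit(times, events)
    assert not fit.median_reached
    assert fit.survival.min() > 0.5


def test_km_no_events_flat_at_one():
    fit = outcomes.km_fit([60.0] * 5, [0] * 5)
    assert np.all(fit.survival == 1.0)
    assert not fit.median_reached


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=20))
def test_km_matches_empirical_survivor_without_censoring(times):
    fit = outcomes.km_fit(times, [1] * len(times))
    for q in (0.1, 0.5, 0.9):
        t = float(np.quantile(times, q))
        assert outcomes.survival_at(fit, t) == pytest.approx(
            empirical_survivor(times, t), abs=1e-12
        )


# --- log-rank --------------------------------------------------------------


def test_logrank_identical_samples_statistic_zero():
    t = [1.0, 2.0, 3.0, 4.0]
    stat, p = outcomes.logrank_test(t, [1] * 4, t, [1] * 4)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_six_subject_term_by_term_oracle():
    """O−E and hypergeometric variance summed by hand at each event time."""
    ta, fa = [1.0, 3.0, 5.0], [1, 1, 0]
    tb, fb = [2.0, 4.0, 6.0], [1, 1, 1]
    times = sorted({t for t, f in zip(ta + tb, fa + fb) if f == 1})
    o_minus_e = var = 0.0
    for t in times:
        n_a = sum(1 for x in ta if x >= t)
        n_b = sum(1 for x in tb if x >= t)
        d_a = sum(1 for x, f in zip(ta, fa) if x == t and f == 1)
        d_b = sum(1 for x, f in zip(tb, fb) if x == t and f == 1)
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    expected = o_minus_e**2 / var
    stat, _ = outcomes.logrank_test(ta, fa, tb, fb)
    assert stat == pytest.approx(expected, rel=1e-9)


def test_logrank_all_censored_raises():
    with pytest.raises(DegenerateInputError):
        outcomes.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


def test_logrank_agrees_with_cox_score_no_ties():
    """With one binary covariate and no ties, the log-rank statistic equals
    the Cox partial-likelihood score test U(0)²/I(0) to 3 decimals."""
    rng = np.random.default_rng(42)
    ta = rng.exponential(10, 20).round(4)
    tb = rng.exponential(20, 20).round(4)
    fa = fb = [1] * 20
    stat, _ = outcomes.logrank_test(ta, fa, tb, fb)
    # score and information at beta=0 computed term by term
    times = np.concatenate([ta, tb])
    x = np.array([0] * 20 + [1] * 20, float)
    order = np.argsort(times)
    u = info = 0.0
    for i in order:
        risk = times >= times[i]
        n = risk.sum()
        mean_x = x[risk].mean()
        u += x[i] - mean_x
        info += mean_x * (1 - mean_x) * 1.0  # single event, no ties
    # hypergeometric variance uses (n-d)/(n-1) = 1 for d=1
    assert stat == pytest.approx(u**2 / info, abs=1e-3)


# --- Cox -------------------------------------------------------------------


def test_cox_null_large_sample():
    rng = np.random.default_rng(1)
    n = 2000
    t = rng.exponential(10, n)
    x = np.repeat([0, 1], n // 2)
    fit = outcomes.cox_fit(t, np.ones(n, int), x)
    assert abs(fit.log_hr) < 3 * fit.se


@pytest.mark.parametrize("seed", range(4))
def test_cox_small_sample_matches_brute_force_maximum(seed):
    rng = np.random.default_rng(seed)
    t = rng.exponential(10, 6) + rng.uniform(0, 0.01, 6)  # no ties
    e = [1, 1, 1, 1, 1, 0]
    x = [0, 1, 0, 1, 0, 1]
    fit = outcomes.cox_fit(t, e, x)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, t, e, x), bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.log_hr == pytest.approx(res.x, abs=1e-4)


def test_cox_invariants_and_ci():
    rng = np.random.default_rng(3)
    t = np.concatenate([rng.exponential(5, 50), rng.exponential(15, 50)])
    e = np.ones(100, int)
    x = np.repeat([0, 1], 50)
    fit = outcomes.cox_fit(t, e, x)
    assert fit.hr == pytest.approx(math.exp(fit.log_hr))
    assert fit.ci95[0] == pytest.approx(math.exp(fit.log_hr - 1.959963984540054 * fit.se))
    assert fit.ci95[1] == pytest.approx(math.exp(fit.log_hr + 1.959963984540054 * fit.se))


def test_cox_efron_and_breslow_agree_without_ties():
    rng = np.random.default_rng(5)
    t = rng.exponential(10, 30)
    e = np.ones(30, int)
    x = np.repeat([0, 1], 15)
    b = outcomes.cox_fit(t, e, x, ties_method="breslow")
    f = outcomes.cox_fit(t, e, x, ties_method="efron")
    assert b.log_hr == pytest.approx(f.log_hr, abs=1e-9)


def test_cox_efron_cross_checked_against_lifelines_with_ties():
    """Independent cross-check: lifelines implements Efron tie handling."""
    from lifelines import CoxPHFitter
    import pandas as pd

    rng = np.random.default_rng(8)
    t = rng.integers(1, 8, 40).astype(float)  # heavy ties
    e = rng.integers(0, 2, 40)
    e[:5] = 1
    x = np.repeat([0, 1], 20)
    ours = outcomes.cox_fit(t, e, x, ties_method="efron")
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
    assert ours.log_hr == pytest.approx(float(cph.params_["x"]), abs=1e-6)


def test_cox_monotone_likelihood_raises():
    # every treated event precedes every control event: likelihood is monotone
    t = [1, 2, 3, 10, 11, 12]
    e = [1, 1, 1, 0, 0, 0]
    x = [1, 1, 1, 0, 0, 0]
    with pytest.raises((ConvergenceError, DegenerateInputError)):
        outcomes.cox_fit(t, e, x)


# --- rank tests ------------------------------------------------------------


def test_rank_tests_identical_paired_degenerate():
    res = outcomes.rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert res.degenerate and res.p_value == 1.0


def test_mann_whitney_complete_separation():
    res = outcomes.rank_tests([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0


def test_wilcoxon_against_exhaustive_sign_flip_enumeration():
    """n=5 paired data: exact p over all 2^5 sign patterns vs the normal
    approximation (documented approximation tolerance)."""
    a = np.array([3.1, 4.5, 2.2, 5.0, 3.9])
    b = np.array([2.0, 3.0, 2.9, 3.1, 2.5])
    d = a - b
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    w_all = []
    for mask in range(2**n):
        signs = [(mask >> i) & 1 for i in range(n)]
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mu = n * (n + 1) / 4
    p_exact = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    res = outcomes.rank_tests(a, b, paired=True)
    assert res.p_value == pytest.approx(p_exact, abs=0.08)


def test_rank_tests_empty_raises():
    with pytest.raises(EmptyInputError):
        outcomes.rank_tests([], [1.0])


# --- sample size -----------------------------------------------------------


def test_unpooled_sample_size_for_study_proportions():
    assert outcomes.sample_size_two_props(0.456, 0.117, 0.05, 0.80, "unpooled") == 24


def test_sample_size_inflation():
    assert outcomes.inflate_sample_size(26, 1.2) == 32


def test_returned_n_achieves_requested_power():
    for variant in ("pooled", "unpooled"):
        n = outcomes.sample_size_two_props(0.456, 0.117, 0.05, 0.80, variant)
        assert outcomes.power_two_props(n, 0.456, 0.117, 0.05, variant) >= 0.80 - 1e-9


def test_sample_size_domain_errors():
    with pytest.raises(ConfigurationError):
        outcomes.sample_size_two_props(0.3, 0.3)
    with pytest.raises(ConfigurationError):
        outcomes.sample_size_two_props(1.2, 0.1)
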