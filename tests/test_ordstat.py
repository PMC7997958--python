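"""Tests for the order-statistic machinery (marginals, roP, joint
survival, minimum-marginal combination, associated-study prediction)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from mpmath import mp

from pvalmeta import (
    InvalidInputError,
    StudyEvidence,
    joint_survival,
    marginal_order_p,
    order_bounds,
    ordmeta_combine,
    predict_associated,
    rop_combine,
)
from pvalmeta.ordstat import (
    _crossing_mp,
    _survival_double,
    log_marginal_order_p,
    ordmeta_pvalues_batch,
)


# ---------------------------------------------------------------------------
# beta marginals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r,n,x,expected",
    [
        (1, 1, 0.3, 0.3),
        (2, 2, 0.5, 0.25),
        (1, 4, 2.80e-08, 1.1199999527811144e-07),  # 1 - (1-x)^4
        (5, 10, 0.2, 0.03279349760000002),  # Beta(5, 6) CDF
    ],
)
def test_marginal_reference_values(r, n, x, expected):
    assert marginal_order_p(r, n, x) == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("r,n,x", [(2, 5, 1e-150), (3, 8, 1e-60), (1, 20, 1e-300)])
def test_marginal_extreme_small_x_against_mpmath(r, n, x):
    """Log-space series keeps relative accuracy where betainc underflows."""
    with mp.workdps(60):
        exact = mp.log(mp.betainc(r, n - r + 1, 0, x, regularized=True))
    assert log_marginal_order_p(r, n, x) == pytest.approx(float(exact), rel=1e-10)


def test_marginal_rank_out_of_range():
    with pytest.raises(InvalidInputError):
        marginal_order_p(0, 3, 0.5)
    with pytest.raises(InvalidInputError):
        marginal_order_p(4, 3, 0.5)


def test_rop_examples():
    assert rop_combine(StudyEvidence(p=[0.4]), 1).p_combined == pytest.approx(0.4)
    # n=2, r=2: F_(2)(x) = x^2 at the 2nd smallest input, 0.9
    assert rop_combine(StudyEvidence(p=[0.9, 0.5]), 2).p_combined == pytest.approx(0.81)
    with pytest.raises(InvalidInputError):
        rop_combine(StudyEvidence(p=[0.1, 0.2]), 3)


# ---------------------------------------------------------------------------
# boundary inversion
# ---------------------------------------------------------------------------

def test_order_bounds_endpoints_and_identity():
    assert np.all(order_bounds(0.0, 5).c == 0.0)
    assert np.all(order_bounds(1.0, 5).c == 1.0)
    assert order_bounds(0.37, 1).c[0] == pytest.approx(0.37, rel=1e-12)


def test_order_bounds_two_study_closed_form():
    c = order_bounds(0.19, 2).c
    assert c[0] == pytest.approx(0.1, rel=1e-10)
    assert c[1] == pytest.approx(np.sqrt(0.19), rel=1e-10)


@pytest.mark.parametrize("alpha", [0.9, 0.3, 1e-3, 1e-12, 1e-30, 1e-250])
@pytest.mark.parametrize("n", [2, 7, 40])
def test_order_bounds_roundtrip_precision(alpha, n):
    """F_(r)(c_r) = alpha to <= 1e-10 relative error, even at extreme alpha."""
    c = order_bounds(alpha, n).c
    assert np.all(np.diff(c) >= -1e-15)
    for r in range(1, n + 1):
        back = np.exp(log_marginal_order_p(r, n, float(c[r - 1])))
        assert back == pytest.approx(alpha, rel=1e-9)


# ---------------------------------------------------------------------------
# joint survival
# ---------------------------------------------------------------------------

def _sympy_survival(c_rationals):
    """Exact nested-integral survival probability (independent oracle).

    n! * int_{c_n}^1 ... int_{c_1}^{t_2} dt_1 ... dt_n in exact rational
    arithmetic.
    """
    import sympy as sp

    n = len(c_rationals)
    ts = sp.symbols(f"t1:{n + 1}")
    expr = sp.Integer(1)
    for i in range(n):
        upper = ts[i + 1] if i + 1 < n else sp.Integer(1)
        expr = sp.integrate(expr, (ts[i], c_rationals[i], upper))
    return sp.factorial(n) * expr


def test_joint_survival_trivial_bounds():
    assert joint_survival([0.0, 0.0, 0.0]) == 1.0
    assert joint_survival([0.2, 0.5, 1.0]) == 0.0


def test_joint_survival_two_study_closed_form():
    # 2 * int_{sqrt(0.19)}^{1} (t2 - 0.1) dt2
    assert joint_survival([0.1, np.sqrt(0.19)]) == pytest.approx(
        0.697177978870813, rel=1e-10
    )


def test_joint_survival_rejects_decreasing_bounds():
    with pytest.raises(InvalidInputError):
        joint_survival([0.5, 0.2])


@pytest.mark.parametrize("n", [2, 3, 4])
def test_joint_survival_matches_exact_nested_integral(n, rng):
    import sympy as sp

    for _ in range(4):
        c = np.sort(rng.uniform(0, 0.9, size=n))
        c_rat = [sp.Rational(int(v * 10**6), 10**6) for v in c]
        exact = float(_sympy_survival(c_rat))
        got = joint_survival(np.array([float(v) for v in c_rat]))
        assert got == pytest.approx(exact, rel=1e-10)


@pytest.mark.parametrize("n", [5, 12, 30])
def test_double_and_mp_crossing_routes_agree(n, rng):
    """The positive-term double recursion and the arbitrary-precision
    first-crossing recursion are independent routes to the same number."""
    alpha = rng.uniform(0.01, 0.3)
    c = order_bounds(alpha, n).c
    S = _survival_double(c)
    cross = float(_crossing_mp(np.log(c), n))
    assert 1.0 - S == pytest.approx(cross, rel=1e-9)


def test_crossing_monte_carlo(rng):
    n, draws = 6, 400_000
    alpha = 0.08
    c = order_bounds(alpha, n).c
    U = np.sort(rng.uniform(size=(draws, n)), axis=1)
    hits = (U <= c[None, :]).any(axis=1).mean()
    p = 1.0 - joint_survival(c)
    se = np.sqrt(p * (1 - p) / draws)
    assert abs(hits - p) < 3 * se


# ---------------------------------------------------------------------------
# ordmeta
# ---------------------------------------------------------------------------

def test_ordmeta_single_study_identity():
    res = ordmeta_combine(StudyEvidence(p=[0.2]))
    assert res.p_combined == pytest.approx(0.2, rel=1e-12)
    assert res.optimal_order == 1


def test_ordmeta_two_study_example():
    res = ordmeta_combine(StudyEvidence(p=[0.1, 0.5]))
    assert res.min_marginal == pytest.approx(0.19, rel=1e-12)
    assert res.optimal_order == 1
    assert res.p_combined == pytest.approx(0.302822021129187, rel=1e-10)


def test_ordmeta_published_locus(bmi_table):
    from pvalmeta import combine_directional

    ev = StudyEvidence(p=[2.60e-04, 0.59, 1.95e-06, 2.80e-08], sign=[1, 1, 1, 1])
    res = combine_directional(ev, "ordmeta", one_tailed=True)
    assert res.p_combined == pytest.approx(1.82e-10, rel=5e-3)


def test_ordmeta_extreme_underflow_reports_high_precision_string():
    ev = StudyEvidence(p=[1e-250, 1e-250, 1e-250])
    res = ordmeta_combine(ev)
    assert res.p_combined >= 0.0
    assert "p_str" in res.extras
    assert float(mp.mpf(res.extras["p_str"])) == pytest.approx(
        res.p_combined, rel=1e-6, abs=1e-320
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(1e-12, 1.0, exclude_max=False), min_size=1, max_size=12)
)
def test_ordmeta_sandwich_bound(p):
    """min marginal <= combined p <= n * min marginal (union bound)."""
    res = ordmeta_combine(StudyEvidence(p=np.asarray(p)))
    n = len(p)
    assert res.p_combined >= res.min_marginal * (1 - 1e-9)
    assert res.p_combined <= min(1.0, n * res.min_marginal) * (1 + 1e-9)


def test_ordmeta_null_uniformity(rng):
    """Combined p of i.i.d. uniforms is itself uniform."""
    reps, n = 3000, 5
    P = rng.uniform(size=(reps, n))
    pc = ordmeta_pvalues_batch(P)
    for q in (0.01, 0.05, 0.10):
        se = np.sqrt(q * (1 - q) / reps)
        assert abs((pc < q).mean() - q) < 3 * se


def test_ordmeta_robust_to_appended_large_pvalue():
    base = ordmeta_combine(StudyEvidence(p=[1e-6, 1e-6]))
    grown = ordmeta_combine(StudyEvidence(p=[1e-6, 1e-6, 0.999]))
    # the appended ~1 input may change p only through n, not the minimum
    assert grown.optimal_order <= 2
    assert grown.p_combined < 5 * base.p_combined


def test_ordmeta_tie_breaks_to_smallest_rank():
    res = ordmeta_combine(StudyEvidence(p=[0.3, 0.3, 0.3, 0.3]))
    marginals = [marginal_order_p(r, 4, 0.3) for r in (1, 2, 3, 4)]
    assert res.optimal_order == int(np.argmin(marginals)) + 1


def test_ordmeta_batch_matches_scalar(rng):
    P = rng.uniform(size=(40, 7))
    batch = ordmeta_pvalues_batch(P)
    scalar = np.array([ordmeta_combine(StudyEvidence(p=row)).p_combined for row in P])
    np.testing.assert_allclose(batch, scalar, rtol=1e-8)


# ---------------------------------------------------------------------------
# associated-study prediction
# ---------------------------------------------------------------------------

def test_predict_single_study_flagged():
    assert predict_associated(StudyEvidence(p=[0.7])).tolist() == [True]


def test_predict_flags_ranks_up_to_optimal():
    mask = predict_associated(StudyEvidence(p=[0.1, 0.5]))
    assert mask.tolist() == [True, False]


def test_predict_published_locus_flags_both_small_cohorts():
    mask = predict_associated(
        StudyEvidence(p=[0.71, 0.39, 2.80e-06, 6.50e-06])
    )
    assert mask.tolist() == [False, False, True, True]


def test_predict_mask_count_equals_optimal_order(rng):
    for _ in range(10):
        p = rng.uniform(size=9)
        res = ordmeta_combine(StudyEvidence(p=p))
        assert res.predicted_mask.sum() == res.optimal_order
        np.testing.assert_array_equal(
            res.predicted_mask, predict_associated(StudyEvidence(p=p))
        )
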