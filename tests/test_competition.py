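"""Two-population fixed points, stability thresholds and heat flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import atpflow as af
from atpflow.competition import jacobian


def _params(r1=1.39e-2, r2=1.53e-2, tau1=72.0, tau2=72.0, K=4.05e21, **kw):
    return af.CompetitionParams(r1=r1, r2=r2, tau1=tau1, tau2=tau2, K=K, **kw)


def _fd_jacobian(cp, Q1, Q2, h_frac=1e-6):
    """Finite-difference Jacobian of rhs2; central differences in the
    interior, second-order one-sided at the Q >= 0 boundary (both exact
    for the quadratic balance up to round-off)."""
    h = h_frac * cp.K
    num = np.empty((2, 2))
    for j in range(2):
        base = (Q1, Q2)[j]

        def f(x):
            args = (x, Q2) if j == 0 else (Q1, x)
            return np.array(af.rhs2(cp, *args))

        if base - h >= 0:
            col = (f(base + h) - f(base - h)) / (2 * h)
        else:
            col = (-3 * f(base) + 4 * f(base + h) - f(base + 2 * h)) / (2 * h)
        num[:, j] = col
    return num


def test_rhs2_fixed_points(calibrated_cp):
    assert af.rhs2(calibrated_cp, 0.0, 0.0) == (0.0, 0.0)
    Qa = calibrated_cp.K * (1.0 - 1.0 / (calibrated_cp.r1 * calibrated_cp.tau1))
    d1, d2 = af.rhs2(calibrated_cp, Qa, 0.0)
    assert d1 == pytest.approx(0.0, abs=1e-9 * calibrated_cp.K / 72.0)
    assert d2 == 0.0


@settings(max_examples=40, derandomize=True)
@given(
    q1=st.floats(min_value=0.0, max_value=2e21),
    q2=st.floats(min_value=0.0, max_value=2e21),
    c=st.floats(min_value=0.0, max_value=2.0),
)
def test_rhs2_index_swap_symmetry(q1, q2, c):
    cp = _params(c=c)
    d1, d2 = af.rhs2(cp, q1, q2)
    s2, s1 = af.rhs2(cp.swapped(), q2, q1)
    assert d1 == pytest.approx(s1, rel=1e-12, abs=1e-3)
    assert d2 == pytest.approx(s2, rel=1e-12, abs=1e-3)


def test_exclusion_state_values(calibrated_cp):
    pts = {fp.label: fp for fp in af.fixed_points(calibrated_cp)}
    assert pts["exclusion-b"].Q2 == pytest.approx(3.735e20, rel=1e-3)
    assert pts["exclusion-b"].Q1 == 0.0
    assert pts["exclusion-a"].Q2 == 0.0


def test_symmetric_exclusion_states_equal():
    cp = _params(r1=2.0 / 72.0, r2=2.0 / 72.0, alpha1=0.0, alpha2=0.0)
    pts = {fp.label: fp for fp in af.fixed_points(cp)}
    assert pts["exclusion-a"].Q1 == pytest.approx(pts["exclusion-b"].Q2, rel=1e-12)


def test_calibrated_verdicts(calibrated_cp):
    """Resident normal state unstable, malignant takeover state stable."""
    pts = {fp.label: fp for fp in af.fixed_points(calibrated_cp)}
    assert not pts["exclusion-a"].stable
    assert pts["exclusion-b"].stable
    rep = af.stability_report(calibrated_cp)
    assert not rep.eq19_holds_for_a
    assert rep.eq19_holds_for_b


def test_non_viable_exclusion_reported_at_zero():
    cp = _params(r1=0.5 / 72.0)
    pts = {fp.label: fp for fp in af.fixed_points(cp)}
    assert pts["exclusion-a"].Q1 == 0.0
    assert not pts["exclusion-a"].viable


def test_interior_point_flagged_beyond_taxonomy():
    # strong asymmetric antagonism admits a positive coexistence solution
    cp = _params(r1=2.0 / 72.0, r2=2.1 / 72.0, alpha1=1e-24, alpha2=5e-23)
    interior = [fp for fp in af.fixed_points(cp) if fp.label == "interior"]
    if interior:
        fp = interior[0]
        assert fp.beyond_paper
        d1, d2 = af.rhs2(cp, fp.Q1, fp.Q2)
        assert abs(d1) < 1e-6 * cp.K / 72.0 and abs(d2) < 1e-6 * cp.K / 72.0
    # without antagonism the linear system is singular: no interior point
    assert all(fp.label != "interior" for fp in af.fixed_points(_params(c=0.0)))


def test_threshold_zero_for_identical_phenotypes():
    cp = _params(r1=1.5 / 72.0, r2=1.5 / 72.0)
    assert af.eq_threshold_exclusion(cp) == pytest.approx(0.0, abs=1e-30)


def test_threshold_calibrated_value(calibrated_cp):
    thr = af.eq_threshold_exclusion(calibrated_cp)
    assert thr == pytest.approx(4.32e-22, rel=1e-3)
    # far above any interaction in the calibrated sweep (c <= 2)
    assert 2.0 * calibrated_cp.r2 / calibrated_cp.K < thr


def test_threshold_undefined_below_viability():
    with pytest.raises(ValueError):
        af.eq_threshold_exclusion(_params(r1=0.5 / 72.0))


@settings(max_examples=40, derandomize=True)
@given(
    rt1=st.floats(min_value=1.05, max_value=5.0),
    rt2=st.floats(min_value=1.05, max_value=5.0),
    log_alpha2=st.floats(min_value=-26.0, max_value=-18.0),
)
def test_threshold_verdict_equals_eigenvalue_verdict(rt1, rt2, log_alpha2):
    """Closed-form stability of state (a) agrees with the Jacobian signs."""
    cp = _params(r1=rt1 / 72.0, r2=rt2 / 72.0, alpha1=0.0, alpha2=10.0**log_alpha2)
    thr = af.eq_threshold_exclusion(cp, "a")
    fp = next(p for p in af.fixed_points(cp) if p.label == "exclusion-a")
    if abs(cp.alpha2 - thr) < 1e-3 * abs(thr):  # skip the marginal boundary
        return
    assert fp.stable == (cp.alpha2 > thr)


def test_origin_eigenvalues_are_net_growth_rates(calibrated_cp):
    origin = next(p for p in af.fixed_points(calibrated_cp) if p.label == "origin")
    eig = af.characteristic_eigenvalues(calibrated_cp, origin)
    expected = sorted(
        [calibrated_cp.r1 - 1.0 / calibrated_cp.tau1, calibrated_cp.r2 - 1.0 / calibrated_cp.tau2]
    )
    assert sorted(ev.real for ev in eig) == pytest.approx(expected, rel=1e-12)


def test_characteristic_eigenvalues_rejects_non_fixed_point(calibrated_cp):
    from atpflow.competition import FixedPoint

    bogus = FixedPoint(Q1=1e20, Q2=1e20, label="origin", eigenvalues=(0j, 0j), stable=False)
    with pytest.raises(ValueError, match="not a fixed point"):
        af.characteristic_eigenvalues(calibrated_cp, bogus)


@settings(max_examples=25, derandomize=True)
@given(
    rt1=st.floats(min_value=1.05, max_value=5.0),
    rt2=st.floats(min_value=1.05, max_value=5.0),
    c=st.floats(min_value=0.0, max_value=2.0),
)
def test_jacobian_matches_finite_differences(rt1, rt2, c):
    cp = _params(r1=rt1 / 72.0, r2=rt2 / 72.0, c=c)
    for fp in af.fixed_points(cp):
        J = jacobian(cp, fp.Q1, fp.Q2)
        num = _fd_jacobian(cp, fp.Q1, fp.Q2)
        np.testing.assert_allclose(num, J, rtol=1e-6, atol=1e-10)
        analytic = sorted(np.linalg.eigvals(J).real)
        assert sorted(ev.real for ev in fp.eigenvalues) == pytest.approx(analytic, rel=1e-12)


def test_total_heat(calibrated_cp):
    cp = calibrated_cp
    assert af.total_heat(cp, 0.0, 0.0) == 0.0
    Q = 8.1e19
    assert af.total_heat(cp, Q, 0.0) == pytest.approx(
        af.heat_curve(cp.population(1), Q), rel=1e-12
    )
    Q1, Q2 = 5e20, 8e20
    shared = 1.0 - (Q1 + Q2) / cp.K
    P1, P2 = cp.r1 * Q1 * shared, cp.r2 * Q2 * shared
    assert af.total_heat(cp, Q1, Q2) == pytest.approx(2.5 * (P1 + P2), rel=1e-12)
    with pytest.raises(ValueError):
        af.total_heat(cp, 0.6 * cp.K, 0.6 * cp.K)


def test_single_population_reduction(calibrated_cp):
    """With Q2 = 0 the competition balance equals the single-population one."""
    pp = calibrated_cp.population(1)
    for Q in (0.0, 1e18, 8.1e19, 2e21):
        d1, d2 = af.rhs2(calibrated_cp, Q, 0.0)
        assert d1 == pytest.approx(af.rhs(pp, Q), rel=1e-12, abs=1e-6)
        assert d2 == 0.0
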