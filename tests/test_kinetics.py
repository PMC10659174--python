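"""Kinetic diagram formulation, parameter mapping and flow bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import atpflow as af


def _kp(E=1.0, NT=1.0, f=1.0, k1=1.0, k2=1.0):
    """Kinetic set closed under the first law by k3 = 0, k4 = k2."""
    return af.KineticParams(E=E, NT=NT, f=f, k0=k1 + k2, k1=k1, k2=k2, k3=0.0, k4=k2)


def test_first_law_constraint_enforced():
    with pytest.raises(ValueError, match="first-law"):
        af.KineticParams(E=1, NT=1, f=1, k0=1.0, k1=1.0, k2=1.0, k3=0.0, k4=1.0)


@pytest.mark.parametrize(
    "NT, f, Q, expected",
    [(4.05e21, 1.0, 0.0, 4.05e21), (4.05e21, 1.0, 4.05e21, 0.0), (4.05e21, 1.0, 8.1e19, 3.969e21)],
)
def test_resource_stock(NT, f, Q, expected):
    assert af.resource_stock(NT, f, Q) == pytest.approx(expected, rel=1e-12)


def test_resource_stock_mass_balance_violation():
    with pytest.raises(ValueError, match="mass-balance"):
        af.resource_stock(1.0, 1.0, 2.0)


def test_kinetic_rhs_fixed_points():
    kp = _kp(NT=3.0, f=1.5, k1=0.7, k2=1.0)
    assert af.kinetic_rhs_single(kp, 0.0) == 0.0
    # with no outflow the stock stalls at resource exhaustion Q = NT/f
    kp0 = af.KineticParams(E=1.0, NT=3.0, f=1.5, k0=0.7, k1=0.7, k2=0.0, k3=0.0, k4=0.0)
    assert af.kinetic_rhs_single(kp0, 3.0 / 1.5) == pytest.approx(0.0, abs=1e-15)


def test_to_ecological_recovers_calibration():
    kp = _kp(NT=4.05e21, f=1.0, k1=3.432e-24 / 1.0, k2=1.0 / 72.0)
    pp = af.to_ecological(kp)
    assert pp.K == pytest.approx(4.05e21, rel=1e-12)
    assert pp.r == pytest.approx(1.39e-2, rel=1e-3)
    assert pp.tau == pytest.approx(72.0, rel=1e-12)


def test_to_ecological_unit_case():
    pp = af.to_ecological(_kp())
    assert (pp.K, pp.r, pp.tau) == (1.0, 1.0, 1.0)


def test_from_ecological_divides_out_gauge():
    pp = af.PopulationParams(r=1.39e-2, tau=72.0, K=4.05e21)
    kp = af.from_ecological(pp, E=1.0, f=1.0)
    assert kp.k1 == pytest.approx(1.39e-2 / 4.05e21, rel=1e-12)
    assert kp.k2 == pytest.approx(1.0 / 72.0, rel=1e-12)
    assert kp.NT == 4.05e21


@settings(max_examples=30, derandomize=True)
@given(
    r=st.floats(min_value=1e-3, max_value=1.0),
    tau=st.floats(min_value=1.0, max_value=200.0),
    K=st.floats(min_value=1.0, max_value=1e22),
    E=st.floats(min_value=0.1, max_value=10.0),
    f=st.floats(min_value=0.1, max_value=10.0),
)
def test_kinetic_and_ecological_rhs_agree(r, tau, K, E, f):
    """Round-trip mapping preserves the dynamics to 1e-12 over [0, K]."""
    pp = af.PopulationParams(r=r, tau=tau, K=K)
    kp = af.from_ecological(pp, E=E, f=f)
    for Q in np.linspace(0.0, K, 21):
        kin = af.kinetic_rhs_single(kp, Q)
        eco = af.rhs(pp, Q)
        assert kin == pytest.approx(eco, rel=1e-12, abs=1e-12 * r * K)


@settings(max_examples=30, derandomize=True)
@given(
    r=st.floats(min_value=1e-3, max_value=1.0),
    tau=st.floats(min_value=1.0, max_value=200.0),
    E=st.floats(min_value=0.1, max_value=10.0),
    f=st.floats(min_value=0.1, max_value=10.0),
)
def test_mapping_round_trip_identity(r, tau, E, f):
    pp = af.PopulationParams(r=r, tau=tau, K=1e20)
    back = af.to_ecological(af.from_ecological(pp, E=E, f=f))
    assert back.r == pytest.approx(pp.r, rel=1e-12)
    assert back.tau == pytest.approx(pp.tau, rel=1e-12)
    assert back.K == pytest.approx(pp.K, rel=1e-12)


def test_flow_ledger_vanishes_at_empty_stock(normal_pp):
    led = af.flow_ledger(normal_pp, 0.0)
    assert led.P == led.R == led.Jin == led.Jh == 0.0


def test_flow_ledger_maximum_power_point():
    # r*tau = 2: the steady state sits at K/2 where P = r*K/4
    pp = af.PopulationParams(r=2.0 / 72.0, tau=72.0, K=4.05e21, eta=0.4)
    led = af.flow_ledger(pp, pp.K / 2.0)
    assert led.P == pytest.approx(pp.r * pp.K / 4.0, rel=1e-12)
    assert led.Jh == pytest.approx(led.P / 0.4, rel=1e-12)
    # steady state: P = R, so the first law closes as Jin = Jh
    assert led.P == pytest.approx(led.R, rel=1e-12)
    assert led.Jin == pytest.approx(led.Jh, rel=1e-12)


def test_heat_partition_sums_exactly(normal_pp):
    for Q in (1e18, 5e20, 2e21):
        led = af.flow_ledger(normal_pp, Q)
        assert led.heat_production + led.heat_consumption == pytest.approx(
            led.P / normal_pp.eta, rel=1e-15
        )


def test_total_heat_independent_of_recycled_fraction():
    """xi only re-partitions heat between production and consumption."""
    base = dict(r=1.39e-2, tau=72.0, K=4.05e21, eta=0.4)
    Q = 8.1e19
    ledgers = [af.flow_ledger(af.PopulationParams(**base, xi=xi), Q) for xi in (0.1, 0.5, 0.9)]
    assert len({led.Jh for led in ledgers}) == 1
    assert len({led.heat_production for led in ledgers}) == 3


def test_flow_ledger_flags_negative_production_heat():
    # near K the production inflow vanishes but turnover heat remains
    pp = af.PopulationParams(r=1.39e-2, tau=72.0, K=4.05e21, eta=0.4, xi=0.1)
    led = af.flow_ledger(pp, 0.999 * pp.K)
    assert led.heat_production < 0
    assert not led.consistent


def test_shared_capacity_requires_equal_fractions():
    kcp = af.KineticCompetitionParams(
        E=1.0, NT=10.0, f1=2.0, f2=2.0, k1=1.0, k2=1.0, k3=1.0, k4=1.0
    )
    assert kcp.shared_K() == 5.0
    kcp2 = af.KineticCompetitionParams(
        E=1.0, NT=10.0, f1=2.0, f2=3.0, k1=1.0, k2=1.0, k3=1.0, k4=1.0
    )
    with pytest.raises(ValueError):
        kcp2.shared_K()
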