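"""Diagram-level kinetic formulation and first-law flow bookkeeping.

The growth model can be written at the level of the stock-flow diagram,
before the ecological parameters are introduced. A cell stock Q draws on a
resource stock N = NT - f*Q (conservation of mass during cycling, with f
the stored fraction of resource per unit stock) and on an external source E
through an autocatalytic production process in which every flow is
proportional to E*N*Q:

    dQ/dt = k1*E*N*Q - k2*Q = k1*E*NT*Q - k1*f*E*Q^2 - k2*Q

The kinetic coefficients partition the process flows subject to the
first-law constraint k0 + k3 = k1 + k4 (total inflow + feedback = net
production + heat). Eliminating N yields logistic growth with the
parameter mapping

    K = NT/f,   r = k1*E*NT,   tau = 1/k2.

E and f are a gauge freedom of this mapping: they are not identifiable from
(r, K, tau) and must be supplied when inverting it.

The :class:`FlowLedger` performs the first-law bookkeeping of the diagram at
a given stock value: primary inflow Jin = P/eta, turnover outflow R = Q/tau
of which a fraction xi is recycled, and total heat Jh = P/eta split between
the production process (P/eta - (1-xi)*R) and the consumption process
((1-xi)*R). xi re-partitions the heat but never changes Jh or the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .single import PopulationParams

__all__ = [
    "KineticParams",
    "KineticCompetitionParams",
    "FlowLedger",
    "resource_stock",
    "kinetic_rhs_single",
    "to_ecological",
    "from_ecological",
    "flow_ledger",
]

#: relative tolerance on the first-law coefficient constraint
_FIRST_LAW_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the single-population autocatalytic cycle.

    Invariant: k0 + k3 = k1 + k4 (first law of thermodynamics applied to
    the production process).
    """

    E: float
    NT: float
    f: float
    k0: float
    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        if self.E <= 0 or self.NT <= 0 or self.f <= 0:
            raise ValueError("E, NT and f must be positive")
        for name in ("k0", "k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lhs, rhs_ = self.k0 + self.k3, self.k1 + self.k4
        if not math.isclose(lhs, rhs_, rel_tol=_FIRST_LAW_RTOL, abs_tol=0.0):
            raise ValueError(
                f"first-law constraint violated: k0+k3={lhs!r} != k1+k4={rhs_!r}"
            )


@dataclass(frozen=True)
class KineticCompetitionParams:
    """Kinetic constants of the two-population competition diagram.

    Production flows P_i = k_i*E*N*Q_i (i = 1, 2) with shared resource
    N = NT - f1*Q1 - f2*Q2, outflows k3*Q1 and k4*Q2, and antagonistic
    interaction flows alpha_i*Q1*Q2. Mapping to a single shared carrying
    capacity requires f1 = f2 (K = NT/f1 = NT/f2).
    """

    E: float
    NT: float
    f1: float
    f2: float
    k1: float
    k2: float
    k3: float
    k4: float
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.E, self.NT, self.f1, self.f2, self.k1, self.k2, self.k3, self.k4) <= 0:
            raise ValueError("E, NT, f1, f2 and k1..k4 must be positive")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("interaction strengths must be nonnegative")

    def shared_K(self) -> float:
        """Shared carrying capacity NT/f; requires f1 = f2."""
        if not math.isclose(self.f1, self.f2, rel_tol=_FIRST_LAW_RTOL):
            raise ValueError("a single shared K requires f1 = f2")
        return self.NT / self.f1


@dataclass(frozen=True)
class FlowLedger:
    """First-law bookkeeping of the single-population diagram at stock Q.

    All flows in ATPeq/h. ``consistent`` is False when the production-heat
    component comes out negative ((1-xi)*R exceeding P/eta), which flags a
    ledger inconsistency at that state rather than aborting.
    ``balance`` reports Jin - (P - R) for users wanting instantaneous
    closure of inflow against net storage.
    """

    Jin: float
    P: float
    R: float
    recycled: float
    heat_production: float
    heat_consumption: float
    Jh: float
    balance: float
    consistent: bool


def resource_stock(NT: float, f: float, Q: float) -> float:
    """Resource stock N = NT - f*Q under mass conservation."""
    if NT <= 0 or f <= 0:
        raise ValueError("NT and f must be positive")
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    N = NT - f * Q
    if N < 0:
        raise ValueError(f"mass-balance violation: N = {N!r} < 0 at Q = {Q!r}")
    return N


def kinetic_rhs_single(kp: KineticParams, Q: float) -> float:
    """Stock balance dQ/dt = k1*E*NT*Q - k1*f*E*Q^2 - k2*Q."""
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    return kp.k1 * kp.E * kp.NT * Q - kp.k1 * kp.f * kp.E * Q * Q - kp.k2 * Q


def to_ecological(kp: KineticParams, eta: float = 0.40, xi: float = 0.5) -> PopulationParams:
    """Map kinetic constants to ecological parameters.

    K = NT/f, r = k1*E*NT, tau = 1/k2. eta and xi are bookkeeping
    parameters of the energy partition, not identified by the kinetics.
    """
    if kp.k2 == 0:
        raise ValueError("k2 = 0 implies infinite turnover time")
    if kp.k1 == 0:
        raise ValueError("k1 = 0 implies zero growth rate")
    return PopulationParams(
        r=kp.k1 * kp.E * kp.NT,
        tau=1.0 / kp.k2,
        K=kp.NT / kp.f,
        eta=eta,
        xi=xi,
    )


def from_ecological(pp: PopulationParams, E: float = 1.0, f: float = 1.0) -> KineticParams:
    """Invert the ecological mapping for given gauge choices E and f.

    NT = K*f, k1 = r/(E*NT), k2 = 1/tau. The remaining coefficients are
    fixed by the convention k3 = 0, k4 = k2 (heat coefficient mirroring the
    outflow) and the first-law closure k0 = k1 + k4.
    """
    if E <= 0 or f <= 0:
        raise ValueError("E and f must be positive")
    NT = pp.K * f
    k1 = pp.r / (E * NT)
    k2 = 1.0 / pp.tau
    k4 = k2
    k3 = 0.0
    k0 = k1 + k4
    return KineticParams(E=E, NT=NT, f=f, k0=k0, k1=k1, k2=k2, k3=k3, k4=k4)


def flow_ledger(pp: PopulationParams, Q: float) -> FlowLedger:
    """Evaluate every diagram flow at stock Q.

    P = r*Q*(1 - Q/K), R = Q/tau, Jin = Jh = P/eta; heat splits into the
    production component P/eta - (1-xi)*R and the consumption component
    (1-xi)*R. In steady state (P = R) Jin = Jh closes the first law.
    """
    if not 0 <= Q <= pp.K:
        raise ValueError("Q must lie in [0, K]")
    P = pp.r * Q * (1.0 - Q / pp.K)
    R = Q / pp.tau
    Jin = P / pp.eta
    Jh = P / pp.eta
    heat_consumption = (1.0 - pp.xi) * R
    heat_production = Jh - heat_consumption
    return FlowLedger(
        Jin=Jin,
        P=P,
        R=R,
        recycled=pp.xi * R,
        heat_production=heat_production,
        heat_consumption=heat_consumption,
        Jh=Jh,
        balance=Jin - (P - R),
        consistent=heat_production >= 0.0,
    )
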