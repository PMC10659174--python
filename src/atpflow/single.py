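"""Single-population analytics of the self-limited autocatalytic cycle.

A cell population holding an energy stock Q (ATPeq) grows by converting a
primary energy inflow into new structure and decays by proteome turnover.
With a shared resource stock N = K - Q enforcing mass balance, the net
dynamics is logistic:

    dQ/dt = P(Q) - R(Q) = r*Q*(1 - Q/K) - Q/tau

where P is the net ATP production inflow, R = Q/tau the biosynthesis
outflow, r the intrinsic growth rate (1/h), K the carrying capacity (ATPeq)
and tau the turnover time (h). The product r*tau controls the steady state
Qss = K*(1 - 1/(r*tau)) and defines a taxonomy of growth regimes relative to
the maximum-power state at Q = K/2 (reached in steady state exactly when
r*tau = 2, where Pss = Pmax = r*K/4).

Stability is summarised by the scalar potential V(Q) with dV/dQ = -dQ/dt,

    V(Q) = r*Q^3/(3K) + Q^2/(2 tau) - r*Q^2/2,

whose well depth at Qss orders the stability of the steady states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationParams",
    "SteadyStateSingle",
    "REGIME_NON_VIABLE",
    "REGIME_SUB_OPTIMAL",
    "REGIME_OPTIMAL",
    "REGIME_SUPER_OPTIMAL",
    "rhs",
    "steady_state",
    "power_curve",
    "heat_curve",
    "max_power",
    "classify_regime",
    "stability_potential",
    "logistic_solution",
]

REGIME_NON_VIABLE = "non-viable"
REGIME_SUB_OPTIMAL = "sub-optimal"
REGIME_OPTIMAL = "optimal"
REGIME_SUPER_OPTIMAL = "super-optimal"

#: relative tolerance for the r*tau == 2 regime boundary
_RT_OPT_RTOL = 1e-9


@dataclass(frozen=True)
class PopulationParams:
    """Energetic parameters of one self-regulating cell population.

    Attributes
    ----------
    r : float
        Intrinsic growth rate, 1/h.
    tau : float
        Proteome turnover time, h.
    K : float
        Carrying capacity, ATPeq.
    eta : float
        ATP-production efficiency, in (0, 1].
    xi : float
        Fraction of the turnover outflow R recycled into the resource
        stock, in (0, 1). Affects only the heat partition, not dynamics.
    """

    r: float
    tau: float
    K: float
    eta: float = 0.40
    xi: float = 0.5

    def __post_init__(self) -> None:
        if self.r <= 0 or self.tau <= 0 or self.K <= 0:
            raise ValueError("r, tau and K must be positive")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if not 0 < self.xi < 1:
            raise ValueError("xi must lie in (0, 1)")

    @property
    def rt(self) -> float:
        """The regime-controlling product r*tau."""
        return self.r * self.tau


@dataclass(frozen=True)
class SteadyStateSingle:
    """Steady state of the single-population model.

    Qss + Nss = K; Pss = Qss/tau; Jh_ss = Pss/eta.
    """

    Qss: float
    Pss: float
    Jh_ss: float
    Nss: float
    regime: str
    V_at_Qss: float


def rhs(pp: PopulationParams, Q):
    """Net stock balance dQ/dt = r*Q*(1 - Q/K) - Q/tau (ATPeq/h)."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Q must be nonnegative")
    out = pp.r * Q * (1.0 - Q / pp.K) - Q / pp.tau
    return out if out.ndim else float(out)


def steady_state(pp: PopulationParams) -> SteadyStateSingle:
    """Analytic steady state Qss = K*(1 - 1/(r*tau)) with derived flows.

    For r*tau <= 1 the only nonnegative stationary stock is extinction; the
    state is reported at zero with regime "non-viable".
    """
    rt = pp.rt
    Qss = pp.K * (1.0 - 1.0 / rt) if rt > 1.0 else 0.0
    Pss = Qss / pp.tau
    return SteadyStateSingle(
        Qss=Qss,
        Pss=Pss,
        Jh_ss=Pss / pp.eta,
        Nss=pp.K - Qss,
        regime=classify_regime(pp.r, pp.tau),
        V_at_Qss=stability_potential(pp, Qss),
    )


def power_curve(pp: PopulationParams, Q):
    """Net production P(Q) = r*Q*(1 - Q/K) over the admissible stock range."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0) or np.any(Q > pp.K):
        raise ValueError("Q must lie in [0, K]")
    out = pp.r * Q * (1.0 - Q / pp.K)
    return out if out.ndim else float(out)


def heat_curve(pp: PopulationParams, Q):
    """Total heat flow Jh(Q) = P(Q)/eta."""
    out = np.asarray(power_curve(pp, Q)) / pp.eta
    return out if out.ndim else float(out)


def max_power(pp: PopulationParams) -> tuple[float, float, float]:
    """Maximum-power state: (Q at maximum, Pmax, optimal r*tau product).

    P(Q) is quadratic with its unique maximum at Q = K/2 where
    Pmax = r*K/4; the steady state sits there exactly when r*tau = 2.
    """
    return pp.K / 2.0, pp.r * pp.K / 4.0, 2.0


def classify_regime(r: float, tau: float) -> str:
    """Growth-regime taxonomy by the product r*tau.

    r*tau <= 1: non-viable (extinction); 1 < r*tau < 2: sub-optimal;
    r*tau = 2 (relative tolerance 1e-9): optimal (maximum power);
    r*tau > 2: super-optimal (overshoot of P and Jh).
    """
    if r <= 0 or tau <= 0:
        raise ValueError("r and tau must be positive")
    rt = r * tau
    if rt <= 1.0:
        return REGIME_NON_VIABLE
    if math.isclose(rt, 2.0, rel_tol=_RT_OPT_RTOL):
        return REGIME_OPTIMAL
    return REGIME_SUB_OPTIMAL if rt < 2.0 else REGIME_SUPER_OPTIMAL


def stability_potential(pp: PopulationParams, Q, normalized: bool = False):
    """Stability potential V(Q) = integral of (R - P) dQ.

    V(Q) = r*Q^3/(3K) + Q^2/(2 tau) - r*Q^2/2, so dV/dQ = -dQ/dt by
    construction; the well at Qss deepens with r*tau. With
    ``normalized=True`` the value is reported as V/K^2 for plotting
    comparability across parameter sets (the raw units are nonphysical,
    ATPeq^2/h-scaled).
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Q must be nonnegative")
    V = pp.r * Q**3 / (3.0 * pp.K) + Q**2 / (2.0 * pp.tau) - pp.r * Q**2 / 2.0
    if normalized:
        V = V / pp.K**2
    return V if V.ndim else float(V)


def logistic_solution(pp: PopulationParams, Q0: float, t):
    """Closed-form trajectory of the stock balance (time in hours).

    The balance is algebraically rho*Q*(1 - Q/Qss) with rho = r - 1/tau and
    Qss = K*(1 - 1/(r*tau)), whose solution is

        Q(t) = Qss / (1 + (Qss/Q0 - 1)*exp(-rho*t)).

    Requires r*tau > 1 and Q0 > 0; serves as the analytic oracle for the
    numerical integrator.
    """
    if Q0 <= 0:
        raise ValueError("Q0 must be positive")
    if pp.rt <= 1.0:
        raise ValueError("closed form requires r*tau > 1")
    t = np.asarray(t, dtype=float)
    rho = pp.r - 1.0 / pp.tau
    Qss = pp.K * (1.0 - 1.0 / pp.rt)
    out = Qss / (1.0 + (Qss / Q0 - 1.0) * np.exp(-rho * t))
    return out if out.ndim else float(out)
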