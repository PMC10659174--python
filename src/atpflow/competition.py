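"""Two-population competition analytics.

Two cell stocks Q1 (normal phenotype) and Q2 (malignant phenotype) compete
for a shared resource N = K - Q1 - Q2 and antagonise each other through
Lotka-Volterra interaction flows:

    dQ1/dt = r1*Q1*(1 - Q1/K - Q2/K) - Q1/tau1 - alpha1*Q1*Q2
    dQ2/dt = r2*Q2*(1 - Q1/K - Q2/K) - Q2/tau2 - alpha2*Q1*Q2

The system has the origin plus two exclusion fixed points,

    (a)  Q1 = K*(1 - 1/(r1*tau1)), Q2 = 0
    (b)  Q2 = K*(1 - 1/(r2*tau2)), Q1 = 0,

whose linear stability follows from the Jacobian eigenvalues. For state (a)
the stability condition reduces to the closed-form threshold

    alpha2 > (r2/K) * [ (1 - 1/(r2*tau2)) / (1 - 1/(r1*tau1)) - 1 ],

which fails under the plasma-cell calibration (alpha_i = c*r_i/K with
c <= 2): the normal-population state is unstable against a single malignant
cell, while state (b) is stable — the analytic backbone of the takeover
regime shift.

Total dissipation is Jh(Q1, Q2) = P1/eta1 + P2/eta2 with P_i the production
inflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .single import PopulationParams

__all__ = [
    "CompetitionParams",
    "FixedPoint",
    "StabilityReport",
    "rhs2",
    "jacobian",
    "fixed_points",
    "eq_threshold_exclusion",
    "characteristic_eigenvalues",
    "total_heat",
    "stability_report",
]

LABEL_ORIGIN = "origin"
LABEL_EXCLUSION_A = "exclusion-a"
LABEL_EXCLUSION_B = "exclusion-b"
LABEL_INTERIOR = "interior"


@dataclass(frozen=True)
class CompetitionParams:
    """Parameters of the two-population competition model.

    alpha1 and alpha2 are the antagonistic interaction strengths
    (1/h/ATPeq); when ``c`` is given they are derived as
    alpha_i = c * r_i / K (interaction scaled to each population's power
    generation, keeping alpha1/alpha2 = r1/r2). ``delta`` is the
    phenomenological efficiency of the interaction flows; it enters only
    heat bookkeeping, never the stock dynamics.
    """

    r1: float
    r2: float
    tau1: float
    tau2: float
    K: float
    alpha1: float = 0.0
    alpha2: float = 0.0
    eta1: float = 0.40
    eta2: float = 0.40
    delta: float = 1.0
    c: float | None = None

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.tau1, self.tau2, self.K) <= 0:
            raise ValueError("rates, turnover times and K must be positive")
        for name in ("eta1", "eta2", "delta"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.c is not None:
            if self.c < 0:
                raise ValueError("c must be nonnegative")
            object.__setattr__(self, "alpha1", self.c * self.r1 / self.K)
            object.__setattr__(self, "alpha2", self.c * self.r2 / self.K)
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("interaction strengths must be nonnegative")

    def swapped(self) -> "CompetitionParams":
        """Relabel the populations (1 <-> 2)."""
        return CompetitionParams(
            r1=self.r2, r2=self.r1, tau1=self.tau2, tau2=self.tau1, K=self.K,
            alpha1=self.alpha2, alpha2=self.alpha1,
            eta1=self.eta2, eta2=self.eta1, delta=self.delta,
        )

    def population(self, index: int) -> PopulationParams:
        """Single-population view of one competitor (Q_other = 0)."""
        if index == 1:
            return PopulationParams(r=self.r1, tau=self.tau1, K=self.K, eta=self.eta1)
        if index == 2:
            return PopulationParams(r=self.r2, tau=self.tau2, K=self.K, eta=self.eta2)
        raise ValueError("index must be 1 or 2")


@dataclass(frozen=True)
class FixedPoint:
    """A stationary state with its linearization.

    ``stable`` is True iff every eigenvalue real part is negative.
    ``viable`` is False for an exclusion state whose r*tau <= 1 (reported
    at zero); ``beyond_paper`` marks the interior coexistence solution,
    which the two-state taxonomy of the model does not cover.
    """

    Q1: float
    Q2: float
    label: str
    eigenvalues: tuple[complex, complex]
    stable: bool
    viable: bool = True
    beyond_paper: bool = False


@dataclass(frozen=True)
class StabilityReport:
    """Fixed points plus the closed-form exclusion-state verdicts."""

    fixed_points: tuple[FixedPoint, ...]
    eq19_rhs: float
    eq19_holds_for_a: bool
    eq19_holds_for_b: bool

    def to_frame(self):
        """Machine-readable table (one row per fixed point)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [fp.label for fp in self.fixed_points],
                "Q1": [fp.Q1 for fp in self.fixed_points],
                "Q2": [fp.Q2 for fp in self.fixed_points],
                "eig1_real": [fp.eigenvalues[0].real for fp in self.fixed_points],
                "eig2_real": [fp.eigenvalues[1].real for fp in self.fixed_points],
                "stable": [fp.stable for fp in self.fixed_points],
                "viable": [fp.viable for fp in self.fixed_points],
            }
        )

    def to_text(self) -> str:
        lines = ["Fixed points and linear stability"]
        for fp in self.fixed_points:
            eig = ", ".join(f"{ev.real:.6e}" for ev in self.eigenvalues_of(fp))
            flags = []
            if not fp.viable:
                flags.append("non-viable")
            if fp.beyond_paper:
                flags.append("beyond two-state taxonomy")
            note = f" [{'; '.join(flags)}]" if flags else ""
            lines.append(
                f"  {fp.label:12s} Q1={fp.Q1:.6e} Q2={fp.Q2:.6e} "
                f"eig_re=({eig}) stable={fp.stable}{note}"
            )
        lines.append(
            f"exclusion-state threshold on alpha2: {self.eq19_rhs:.6e} 1/h/ATPeq "
            f"(state a stable: {self.eq19_holds_for_a}; "
            f"state b stable: {self.eq19_holds_for_b})"
        )
        return "\n".join(lines)

    @staticmethod
    def eigenvalues_of(fp: FixedPoint) -> tuple[complex, complex]:
        return fp.eigenvalues


def rhs2(cp: CompetitionParams, Q1, Q2):
    """Coupled stock balances (dQ1/dt, dQ2/dt) in ATPeq/h."""
    Q1 = np.asarray(Q1, dtype=float)
    Q2 = np.asarray(Q2, dtype=float)
    if np.any(Q1 < 0) or np.any(Q2 < 0):
        raise ValueError("stocks must be nonnegative")
    shared = 1.0 - Q1 / cp.K - Q2 / cp.K
    d1 = cp.r1 * Q1 * shared - Q1 / cp.tau1 - cp.alpha1 * Q1 * Q2
    d2 = cp.r2 * Q2 * shared - Q2 / cp.tau2 - cp.alpha2 * Q1 * Q2
    if d1.ndim == 0:
        return float(d1), float(d2)
    return d1, d2


def jacobian(cp: CompetitionParams, Q1: float, Q2: float) -> np.ndarray:
    """Analytic Jacobian of the coupled balances at (Q1, Q2)."""
    J11 = cp.r1 * (1.0 - 2.0 * Q1 / cp.K - Q2 / cp.K) - 1.0 / cp.tau1 - cp.alpha1 * Q2
    J12 = -(cp.r1 / cp.K + cp.alpha1) * Q1
    J21 = -(cp.r2 / cp.K + cp.alpha2) * Q2
    J22 = cp.r2 * (1.0 - Q1 / cp.K - 2.0 * Q2 / cp.K) - 1.0 / cp.tau2 - cp.alpha2 * Q1
    return np.array([[J11, J12], [J21, J22]])


def _fp(cp: CompetitionParams, Q1: float, Q2: float, label: str,
        viable: bool = True, beyond_paper: bool = False) -> FixedPoint:
    eig = np.linalg.eigvals(jacobian(cp, Q1, Q2))
    eig = tuple(complex(ev) for ev in eig)
    stable = all(ev.real < 0 for ev in eig)
    return FixedPoint(Q1=Q1, Q2=Q2, label=label, eigenvalues=eig,
                      stable=stable, viable=viable, beyond_paper=beyond_paper)


def fixed_points(cp: CompetitionParams) -> list[FixedPoint]:
    """All stationary states with their Jacobian eigenvalues.

    Always returns the origin and the two exclusion states (an exclusion
    state whose r*tau <= 1 is reported at zero with ``viable=False``). The
    interior solution of the 2x2 linear coexistence system is appended,
    flagged ``beyond_paper``, whenever it exists with both coordinates
    strictly positive; with alpha1 = alpha2 = 0 the system is singular and
    no interior point is reported.
    """
    pts = [_fp(cp, 0.0, 0.0, LABEL_ORIGIN)]

    rt1, rt2 = cp.r1 * cp.tau1, cp.r2 * cp.tau2
    Qa = cp.K * (1.0 - 1.0 / rt1) if rt1 > 1.0 else 0.0
    pts.append(_fp(cp, Qa, 0.0, LABEL_EXCLUSION_A, viable=rt1 > 1.0))
    Qb = cp.K * (1.0 - 1.0 / rt2) if rt2 > 1.0 else 0.0
    pts.append(_fp(cp, 0.0, Qb, LABEL_EXCLUSION_B, viable=rt2 > 1.0))

    # interior: r_i*(1 - (Q1+Q2)/K) - 1/tau_i - alpha_i*Q_other = 0
    A = np.array(
        [
            [cp.r1 / cp.K, cp.r1 / cp.K + cp.alpha1],
            [cp.r2 / cp.K + cp.alpha2, cp.r2 / cp.K],
        ]
    )
    b = np.array([cp.r1 - 1.0 / cp.tau1, cp.r2 - 1.0 / cp.tau2])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = max(abs(A).max(), 1e-300)
    if abs(det) > 1e-12 * scale * scale:
        Q1i, Q2i = np.linalg.solve(A, b)
        if Q1i > 0 and Q2i > 0:
            pts.append(_fp(cp, float(Q1i), float(Q2i), LABEL_INTERIOR, beyond_paper=True))
    return pts


def eq_threshold_exclusion(cp: CompetitionParams, state: str = "a") -> float:
    """Closed-form interaction threshold stabilising an exclusion state.

    For state (a) (population 1 alone at its steady state) the resident is
    stable against invasion by population 2 iff

        alpha2 > (r2/K) * [ (1 - 1/(r2*tau2)) / (1 - 1/(r1*tau1)) - 1 ].

    ``state="b"`` gives the index-swapped condition on alpha1.
    """
    if state == "b":
        return eq_threshold_exclusion(cp.swapped(), state="a")
    if state != "a":
        raise ValueError("state must be 'a' or 'b'")
    rt1, rt2 = cp.r1 * cp.tau1, cp.r2 * cp.tau2
    if rt1 <= 1.0:
        raise ValueError("threshold undefined: resident population has r1*tau1 <= 1")
    return (cp.r2 / cp.K) * ((1.0 - 1.0 / rt2) / (1.0 - 1.0 / rt1) - 1.0)


def characteristic_eigenvalues(
    cp: CompetitionParams, fp: FixedPoint, rtol: float = 1e-6
) -> tuple[complex, complex]:
    """Eigenvalues of the analytic Jacobian at a verified fixed point.

    The input must satisfy |dQ/dt| < rtol * K/min(tau1, tau2) in both
    components (a scale-aware residual check). For exclusion states the
    Jacobian is triangular and the eigenvalues real.
    """
    d1, d2 = rhs2(cp, fp.Q1, fp.Q2)
    tol = rtol * cp.K / min(cp.tau1, cp.tau2)
    if abs(d1) > tol or abs(d2) > tol:
        raise ValueError(
            f"({fp.Q1!r}, {fp.Q2!r}) is not a fixed point: residual ({d1!r}, {d2!r})"
        )
    eig = np.linalg.eigvals(jacobian(cp, fp.Q1, fp.Q2))
    return tuple(complex(ev) for ev in eig)


def total_heat(cp: CompetitionParams, Q1, Q2):
    """Total heat flow Jh = P1/eta1 + P2/eta2 (ATPeq/h)."""
    Q1 = np.asarray(Q1, dtype=float)
    Q2 = np.asarray(Q2, dtype=float)
    if np.any(Q1 < 0) or np.any(Q2 < 0):
        raise ValueError("stocks must be nonnegative")
    if np.any(Q1 + Q2 > cp.K):
        raise ValueError("Q1 + Q2 exceeds K: shared resource would be negative")
    shared = 1.0 - Q1 / cp.K - Q2 / cp.K
    P1 = cp.r1 * Q1 * shared
    P2 = cp.r2 * Q2 * shared
    out = P1 / cp.eta1 + P2 / cp.eta2
    return out if out.ndim else float(out)


def stability_report(cp: CompetitionParams) -> StabilityReport:
    """Fixed points, eigenvalues and the closed-form exclusion verdicts."""
    pts = fixed_points(cp)
    thr_a = eq_threshold_exclusion(cp, "a")
    holds_a = cp.alpha2 > thr_a
    try:
        thr_b = eq_threshold_exclusion(cp, "b")
        holds_b = cp.alpha1 > thr_b
    except ValueError:
        holds_b = False
    return StabilityReport(
        fixed_points=tuple(pts),
        eq19_rhs=thr_a,
        eq19_holds_for_a=holds_a,
        eq19_holds_for_b=holds_b,
    )
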