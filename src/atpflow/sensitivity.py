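"""One-at-a-time sweeps and analytic steady-state sensitivities.

Numerical sensitivity follows the one-at-a-time (OAT) protocol: a base
scenario is re-integrated once per grid value with a single named parameter
changed, and summary outputs (extinction time, long-time stocks, steady
flows) are tabulated. Rows are computed independently — no warm starting —
so each row equals a plain scenario run.

Analytic sensitivities of the single-population steady state follow from
differentiating Qss = K*(1 - 1/(r*tau)) and Pss = Qss/tau:

    dQss/dr   = K/(r^2*tau)        dQss/dtau = K/(r*tau^2)
    dPss/dr   = K/(r^2*tau^2)      dPss/dtau = -(K/tau^2)*(1 - 2/(r*tau))

with the scaling identity r*dQss/dr = tau*dQss/dtau = K/(r*tau).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .competition import CompetitionParams
from .single import PopulationParams, steady_state
from .simulate import Scenario, detect_regime_shift, integrate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "oat_sweep",
    "analytic_sensitivity_Qss",
    "analytic_sensitivity_Pss",
]

#: outputs recordable by a sweep
_OUTPUTS = ("extinction_time", "Q1_final", "Q2_final", "Q_final", "Pss", "Jh_final")


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep: vary ``parameter`` over ``values`` on ``base``.

    ``parameter`` names a field of the base scenario's parameter set
    (e.g. "r2", "tau2", "c", "alpha1", "r", "tau") or an initial stock
    ("Q0", "Q1_0", "Q2_0"). ``outputs`` selects recorded columns from
    {extinction_time, Q1_final, Q2_final, Q_final, Pss, Jh_final}.
    """

    parameter: str
    values: tuple[float, ...]
    base: Scenario
    outputs: tuple[str, ...] = ("extinction_time", "Q1_final", "Q2_final")

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("sweep grid must be non-empty")
        if self.parameter not in ("Q0", "Q1_0", "Q2_0") and not hasattr(
            self.base.params, self.parameter
        ):
            raise ValueError(
                f"unknown parameter {self.parameter!r} for model {self.base.model!r}"
            )
        unknown = set(self.outputs) - set(_OUTPUTS)
        if unknown:
            raise ValueError(f"unknown outputs: {sorted(unknown)}")


@dataclass(frozen=True)
class SweepResult:
    """Tabulated sweep rows, one per grid value, in grid order."""

    spec: SweepSpec
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def _with_parameter(scn: Scenario, name: str, value: float) -> Scenario:
    if name in ("Q0", "Q1_0", "Q2_0"):
        return replace(scn, **{name: value})
    p = scn.params
    if not hasattr(p, name):
        raise ValueError(f"unknown parameter {name!r} for model {scn.model!r}")
    # when c parametrizes the alphas, replace() re-derives them for the new value
    p = replace(p, **{name: value})
    return replace(scn, params=p)


def oat_sweep(spec: SweepSpec) -> SweepResult:
    """Run the base scenario once per grid value and tabulate outputs.

    Inadmissible grid values (rejected by parameter validation or by the
    integrator) yield a row flagged ``ok=False`` with empty outputs; the
    sweep continues.
    """
    rows = []
    for v in spec.values:
        row: dict = {"parameter": spec.parameter, "value": v, "ok": True}
        try:
            scn = _with_parameter(spec.base, spec.parameter, v)
            tr = integrate(scn)
            if scn.model == "competition":
                if "extinction_time" in spec.outputs:
                    rep = detect_regime_shift(tr)
                    row["extinction_time"] = rep.extinction_time_Q1
                if "Q1_final" in spec.outputs:
                    row["Q1_final"] = float(tr.Q1[-1])
                if "Q2_final" in spec.outputs:
                    row["Q2_final"] = float(tr.Q2[-1])
            else:
                if "Q_final" in spec.outputs:
                    row["Q_final"] = float(tr.Q[-1])
                if "Pss" in spec.outputs:
                    row["Pss"] = steady_state(scn.params).Pss
            if "Jh_final" in spec.outputs:
                row["Jh_final"] = float(tr.Jh[-1])
        except (ValueError, TypeError) as exc:
            row["ok"] = False
            row["error"] = str(exc)
        rows.append(row)
    return SweepResult(spec=spec, table=pd.DataFrame(rows))


def analytic_sensitivity_Qss(pp: PopulationParams) -> dict[str, float]:
    """Partial derivatives of the steady-state stock Qss.

    Returns {"dQss_dr": K/(r^2*tau), "dQss_dtau": K/(r*tau^2)}; defined
    only in the viable regime r*tau > 1.
    """
    if pp.rt <= 1.0:
        raise ValueError("sensitivities undefined: steady state at the extinction boundary")
    return {
        "dQss_dr": pp.K / (pp.r**2 * pp.tau),
        "dQss_dtau": pp.K / (pp.r * pp.tau**2),
    }


def analytic_sensitivity_Pss(pp: PopulationParams) -> dict[str, float]:
    """Partial derivatives of the steady-state power Pss = Qss/tau."""
    if pp.rt <= 1.0:
        raise ValueError("sensitivities undefined: steady state at the extinction boundary")
    return {
        "dPss_dr": pp.K / (pp.r**2 * pp.tau**2),
        "dPss_dtau": -(pp.K / pp.tau**2) * (1.0 - 2.0 / pp.rt),
    }
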