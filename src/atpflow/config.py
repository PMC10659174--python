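"""Scenario configuration files.

A scenario is a single YAML mapping with explicit unit suffixes in key
names (the model mixes hours for rates and years for horizons, so units
are spelled out to prevent mistakes). Unknown keys are rejected.

Single-population scenario::

    model: single
    params:
      r_per_h: 1.39e-2
      tau_h: 72.0
      K_atpeq: 4.05e21
      eta: 0.4
      xi: 0.5
    initial:
      Q_atpeq: 8.1e19
    integration:
      t_end_years: 60.0
      dt_out_years: 0.01

Competition scenario: ``params`` carries r1_per_h, r2_per_h, tau1_h,
tau2_h, K_atpeq, eta1, eta2, delta and either explicit interaction
strengths alpha1_per_h_atpeq / alpha2_per_h_atpeq or the scale
``interaction_scale_c`` (alpha_i = c*r_i/K); ``initial`` carries Q1_atpeq
and Q2_atpeq. An optional ``sweep`` block (parameter, values) configures a
one-at-a-time sweep, and an optional ``kinetic`` block supplies
diagram-level constants (E, NT, f, k0..k4) instead of ecological ones for
the single model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .competition import CompetitionParams
from .kinetics import KineticParams, to_ecological
from .simulate import ONE_CELL_ATPEQ, Scenario
from .single import PopulationParams

__all__ = ["Config", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised on schema violations, with a field-level message."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SingleParamsBlock(_Strict):
    r_per_h: Optional[float] = None
    tau_h: Optional[float] = None
    K_atpeq: Optional[float] = None
    eta: float = 0.40
    xi: float = 0.5


class KineticBlock(_Strict):
    E: float
    NT: float
    f: float
    k0: float
    k1: float
    k2: float
    k3: float
    k4: float


class CompetitionParamsBlock(_Strict):
    r1_per_h: float
    r2_per_h: float
    tau1_h: float
    tau2_h: float
    K_atpeq: float
    alpha1_per_h_atpeq: Optional[float] = None
    alpha2_per_h_atpeq: Optional[float] = None
    interaction_scale_c: Optional[float] = None
    eta1: float = 0.40
    eta2: float = 0.40
    delta: float = 1.0


class InitialBlock(_Strict):
    Q_atpeq: Optional[float] = None
    Q1_atpeq: Optional[float] = None
    Q2_atpeq: Optional[float] = None


class IntegrationBlock(_Strict):
    t_end_years: float = 60.0
    dt_out_years: float = 0.01
    extinction_threshold_atpeq: float = ONE_CELL_ATPEQ


class SweepBlock(_Strict):
    parameter: str
    values: tuple[float, ...]
    outputs: tuple[str, ...] = ("extinction_time", "Q1_final", "Q2_final")


class Config(_Strict):
    """Validated scenario configuration."""

    model: Literal["single", "competition"]
    params: SingleParamsBlock | CompetitionParamsBlock
    initial: InitialBlock
    integration: IntegrationBlock = IntegrationBlock()
    kinetic: Optional[KineticBlock] = None
    sweep: Optional[SweepBlock] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "Config":
        if self.model == "single":
            if not isinstance(self.params, SingleParamsBlock):
                raise ValueError("single model requires the single-population params block")
            if self.initial.Q_atpeq is None:
                raise ValueError("single model requires initial.Q_atpeq")
            ecological = all(
                v is not None
                for v in (self.params.r_per_h, self.params.tau_h, self.params.K_atpeq)
            )
            if not ecological and self.kinetic is None:
                raise ValueError(
                    "single model requires either params.{r_per_h,tau_h,K_atpeq} "
                    "or a kinetic block"
                )
        else:
            if not isinstance(self.params, CompetitionParamsBlock):
                raise ValueError("competition model requires the competition params block")
            if self.initial.Q1_atpeq is None or self.initial.Q2_atpeq is None:
                raise ValueError("competition model requires initial.Q1_atpeq and Q2_atpeq")
            p = self.params
            explicit = p.alpha1_per_h_atpeq is not None or p.alpha2_per_h_atpeq is not None
            if explicit and p.interaction_scale_c is not None:
                raise ValueError(
                    "give either explicit alphas or interaction_scale_c, not both"
                )
        return self

    def population_params(self) -> PopulationParams:
        if self.model != "single":
            raise ConfigError("not a single-population scenario")
        if self.kinetic is not None and self.params.r_per_h is None:
            kb = self.kinetic
            kp = KineticParams(E=kb.E, NT=kb.NT, f=kb.f, k0=kb.k0, k1=kb.k1,
                               k2=kb.k2, k3=kb.k3, k4=kb.k4)
            return to_ecological(kp, eta=self.params.eta, xi=self.params.xi)
        return PopulationParams(
            r=self.params.r_per_h, tau=self.params.tau_h, K=self.params.K_atpeq,
            eta=self.params.eta, xi=self.params.xi,
        )

    def competition_params(self) -> CompetitionParams:
        if self.model != "competition":
            raise ConfigError("not a competition scenario")
        p = self.params
        kwargs = dict(
            r1=p.r1_per_h, r2=p.r2_per_h, tau1=p.tau1_h, tau2=p.tau2_h,
            K=p.K_atpeq, eta1=p.eta1, eta2=p.eta2, delta=p.delta,
        )
        if p.interaction_scale_c is not None:
            kwargs["c"] = p.interaction_scale_c
        else:
            kwargs["alpha1"] = p.alpha1_per_h_atpeq or 0.0
            kwargs["alpha2"] = p.alpha2_per_h_atpeq or 0.0
        return CompetitionParams(**kwargs)

    def scenario(self) -> Scenario:
        """Build the runnable scenario this config describes."""
        if self.model == "single":
            return Scenario(
                model="single",
                params=self.population_params(),
                Q0=self.initial.Q_atpeq,
                t_end=self.integration.t_end_years,
                dt_out=self.integration.dt_out_years,
            )
        return Scenario(
            model="competition",
            params=self.competition_params(),
            Q1_0=self.initial.Q1_atpeq,
            Q2_0=self.initial.Q2_atpeq,
            t_end=self.integration.t_end_years,
            dt_out=self.integration.dt_out_years,
        )


def load_config(path) -> Config:
    """Parse and validate a YAML scenario file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at the top level")
    # steer the params union by the model key so error messages name fields
    try:
        return Config.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"{path}: {details}") from exc


def dump_config(cfg: Config, path) -> None:
    """Write a config back to YAML (round-trips to an identical object)."""
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=False)
    )
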