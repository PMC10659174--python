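"""Unit conversions and parameter-estimation recipes.

Cell stocks are measured on a common energetic scale: one cell is equated
with the number of ATP molecules needed to build it (the *ATP-equivalent*,
ATPeq), and one ATP hydrolysis is worth about 1e-19 J. These two constants
convert between cell counts, ATPeq stocks, and joules.

The calibration recipes turn literature-level observables (proteome turnover
time, relative growth rate of a malignant phenotype, body cell counts) into
the rate and capacity parameters of the growth model:

* normal phenotype: ``r_n ~= 1 / (tau * (1 - Qss/K))``, i.e. the growth rate
  that balances turnover at the observed steady-state occupancy;
* malignant phenotype: ``r_m = (1 + RGR) / tau``, an increment over pure
  turnover parametrized by the relative growth rate RGR (a dimensionless
  fraction of the turnover rate; this reading reproduces the calibrated
  endpoints 1.43e-2 and 1.53e-2 per hour at RGR = 3% and 10% with tau = 72 h);
* carrying capacity: (cells in the body) x (bone-marrow volume fraction)
  x (ATPeq per cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConversionConstants",
    "CalibrationDefaults",
    "DEFAULT_CONSTANTS",
    "DEFAULT_CALIBRATION",
    "cells_to_atpeq",
    "atpeq_to_joules",
    "growth_rate_normal",
    "growth_rate_malignant",
    "carrying_capacity",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Physical constants linking cells, ATPeq and joules.

    Attributes
    ----------
    atp_per_cell : float
        ATP-equivalents stored in one cell (default 5e10).
    joules_per_atp : float
        Free energy per ATP molecule in joules (default 1e-19).
    """

    atp_per_cell: float = 5e10
    joules_per_atp: float = 1e-19

    def __post_init__(self) -> None:
        if self.atp_per_cell <= 0 or self.joules_per_atp <= 0:
            raise ValueError("conversion constants must be strictly positive")


@dataclass(frozen=True)
class CalibrationDefaults:
    """Shipped calibration for human plasma cells in the bone marrow.

    Attributes
    ----------
    K : float
        Carrying capacity of the bone-marrow niche, ATPeq.
    qss_fraction : float
        Normal-phenotype steady-state occupancy as a fraction of K.
    tau : float
        Proteome turnover time, hours.
    eta : float
        ATP-production efficiency (oxidative phosphorylation), dimensionless.
    rgr_grid : tuple of float
        Malignancy grid of relative growth rates (fractions).
    """

    K: float = 4.05e21
    qss_fraction: float = 0.02
    tau: float = 72.0
    eta: float = 0.40
    rgr_grid: tuple[float, ...] = (0.03, 0.04, 0.06, 0.10)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0 < self.qss_fraction < 1:
            raise ValueError("qss_fraction must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if any(not 0 < g < 1 for g in self.rgr_grid):
            raise ValueError("rgr_grid values must lie in (0, 1)")


DEFAULT_CONSTANTS = ConversionConstants()
DEFAULT_CALIBRATION = CalibrationDefaults()


def cells_to_atpeq(n_cells: float, consts: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a cell count to its ATP-equivalent energy stock."""
    if n_cells < 0:
        raise ValueError(f"cell count must be nonnegative, got {n_cells}")
    return n_cells * consts.atp_per_cell


def atpeq_to_joules(q: float, consts: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert an ATPeq stock to joules."""
    if q < 0:
        raise ValueError(f"energy must be nonnegative, got {q}")
    return q * consts.joules_per_atp


def growth_rate_normal(tau: float, qss_fraction: float) -> float:
    """Intrinsic growth rate of the normal phenotype, per hour.

    Solves the logistic steady state for r given the observed occupancy
    fraction Qss/K: r = 1 / (tau * (1 - Qss/K)).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 <= qss_fraction < 1:
        raise ValueError("qss_fraction must lie in [0, 1)")
    return 1.0 / (tau * (1.0 - qss_fraction))


def growth_rate_malignant(rgr: float, tau: float) -> float:
    """Intrinsic growth rate of a malignant phenotype, per hour.

    r_m = (1 + RGR) / tau: the relative growth rate RGR is a malignancy-
    dependent fractional increment over the pure turnover rate 1/tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 <= rgr < 1:
        raise ValueError("rgr must lie in [0, 1)")
    return (1.0 + rgr) / tau


def carrying_capacity(
    n_body_cells: float,
    bm_fraction: float,
    consts: ConversionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Carrying capacity of the niche in ATPeq.

    (number of cells in the body) x (bone-marrow volume fraction)
    x (ATPeq per cell).
    """
    if n_body_cells <= 0:
        raise ValueError("n_body_cells must be positive")
    if not 0 < bm_fraction <= 1:
        raise ValueError("bm_fraction must lie in (0, 1]")
    return n_body_cells * bm_fraction * consts.atp_per_cell
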