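"""First-order Arrhenius thermal-damage kinetics.

Damage accumulates as Ω(t) = ∫ A·exp(−Ea/(R·T(t))) dt over an absolute
temperature history; the surviving cell fraction is SF = exp(−Ω).  Two
parameter presets are shipped: ``CELL_DEATH`` (A = 2.984e80 1/s,
Ea = 5.06e5 J/mol) for the ablation kill boundary, where Ω ≥ 6.9 marks
99.9% cell kill, and ``VASCULAR`` (A = 1.98e106 1/s, Ea = 6.67e5 J/mol) for
capillary coagulation, where C_f = 1 − exp(−Ω) is the occluded flow fraction.

The pre-exponential factors are astronomically large, so the integrand is
always evaluated in log space as exp(ln A − Ea/(R·T)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import LabelMask, ScalarMap

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusParams",
    "CELL_DEATH",
    "VASCULAR",
    "KILL_THRESHOLD_OMEGA",
    "damage_rate",
    "omega_integral",
    "surviving_fraction",
    "coagulation_fraction",
    "kill_mask",
    "celsius_to_kelvin",
]

GAS_CONSTANT = 8.314  # J/mol/K

#: Ω at the ablation boundary (SF = exp(−6.9) ≈ 0.001, i.e. 99.9% kill)
KILL_THRESHOLD_OMEGA = 6.9


@dataclass(frozen=True)
class ArrheniusParams:
    pre_exponential_A: float  # 1/s
    activation_energy_Ea: float  # J/mol

    def __post_init__(self) -> None:
        if self.pre_exponential_A <= 0 or self.activation_energy_Ea <= 0:
            raise ValueError("A and Ea must be positive")

    @property
    def log_A(self) -> float:
        return math.log(self.pre_exponential_A)


CELL_DEATH = ArrheniusParams(pre_exponential_A=2.984e80, activation_energy_Ea=5.06e5)
VASCULAR = ArrheniusParams(pre_exponential_A=1.98e106, activation_energy_Ea=6.67e5)


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=np.float64) + 273.15


def damage_rate(temperature_K, params: ArrheniusParams):
    """Instantaneous damage rate A·exp(−Ea/(R·T)) in 1/s, log-space safe.

    Accepts scalars or arrays; T = 0 K maps to rate 0.
    """
    t = np.asarray(temperature_K, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("absolute temperature must be >= 0 K")
    with np.errstate(divide="ignore"):
        log_rate = params.log_A - params.activation_energy_Ea / (
            GAS_CONSTANT * np.where(t > 0, t, np.inf)
        )
    out = np.exp(log_rate)
    if np.ndim(temperature_K) == 0:
        return float(out)
    return out


def omega_integral(times_s, temperatures_K, params: ArrheniusParams) -> float:
    """Trapezoidal Ω over a sampled temperature history.

    ``times_s`` must be strictly increasing; Ω is additive over concatenated
    sub-intervals by construction of the trapezoid rule.
    """
    t = np.asarray(times_s, dtype=np.float64)
    temp = np.asarray(temperatures_K, dtype=np.float64)
    if t.ndim != 1 or t.shape != temp.shape:
        raise ValueError("times and temperatures must be 1D arrays of equal length")
    if t.size < 2:
        return 0.0
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(damage_rate(temp, params), t))


def surviving_fraction(omega) -> float | np.ndarray:
    """SF = exp(−Ω) for Ω >= 0."""
    om = np.asarray(omega, dtype=np.float64)
    if np.any(om < 0):
        raise ValueError("omega must be >= 0")
    out = np.exp(-om)
    return float(out) if np.ndim(omega) == 0 else out


def coagulation_fraction(times_s, temperatures_K, params: ArrheniusParams = VASCULAR) -> float:
    """Fraction of capillary flow occluded: C_f = 1 − exp(−Ω_vascular) ∈ [0, 1)."""
    return 1.0 - math.exp(-omega_integral(times_s, temperatures_K, params))


def kill_mask(omega_map: ScalarMap, threshold: float = KILL_THRESHOLD_OMEGA) -> LabelMask:
    """Voxels at or beyond the damage threshold (Ω >= threshold)."""
    if np.any(omega_map.values < 0):
        raise ValueError("omega map contains negative values")
    return LabelMask(omega_map.grid, omega_map.values >= threshold)
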