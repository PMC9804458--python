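"""Bioenergetic predation rates.

A predator's daily energy expenditure follows a field-metabolic-rate power
law, ``demand = coeff * mass**expo`` (kJ/day).  Dividing the share of that
demand met by a given prey stage by the energy contained in one prey
individual yields a constant per-capita daily consumption rate: predation
carries no satiation, handling time, or prey-density dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnergeticsParams",
    "PredationRates",
    "metabolic_demand",
    "predation_rate",
    "compute_rates",
]


@dataclass(frozen=True)
class EnergeticsParams:
    """Predator/prey masses, prey energy densities, diet fractions and
    allometric constants.

    Masses in g/individual, energy densities in kJ/g; diet fractions are the
    proportion of the predator's daily energy intake supplied by each
    tropicbird stage (A adult, H hatchling, E egg; C cat, R rat).
    """

    mass_C: float
    mass_R: float
    mass_A: float
    mass_H: float
    mass_E: float
    energy_A: float
    energy_H: float
    energy_E: float
    preypref_A_C: float
    preypref_H_C: float
    preypref_H_R: float
    preypref_E_R: float
    allom_coeff_C: float = 1.67
    allom_exp_C: float = 0.869
    allom_coeff_R: float = 5.48
    allom_exp_R: float = 0.712

    def __post_init__(self) -> None:
        for name in ("mass_C", "mass_R", "mass_A", "mass_H", "mass_E",
                     "energy_A", "energy_H", "energy_E",
                     "allom_coeff_C", "allom_coeff_R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("preypref_A_C", "preypref_H_C", "preypref_H_R",
                     "preypref_E_R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.preypref_A_C + self.preypref_H_C > 1.0 + 1e-12:
            raise ValueError("cat diet fractions sum to more than 1")
        if self.preypref_H_R + self.preypref_E_R > 1.0 + 1e-12:
            raise ValueError("rat diet fractions sum to more than 1")

    @property
    def metdemand_C(self) -> float:
        """Cat daily metabolic demand [kJ/day]."""
        return metabolic_demand(self.mass_C, self.allom_coeff_C, self.allom_exp_C)

    @property
    def metdemand_R(self) -> float:
        """Rat daily metabolic demand [kJ/day]."""
        return metabolic_demand(self.mass_R, self.allom_coeff_R, self.allom_exp_R)


@dataclass(frozen=True)
class PredationRates:
    """Per-capita daily consumption of each tropicbird stage.

    ``p_A_C``: adult birds per cat per day; ``p_H_C``: hatchlings per cat
    per day; ``p_H_R``: hatchlings per rat per day; ``p_E_R``: eggs per rat
    per day.
    """

    p_A_C: float
    p_H_C: float
    p_H_R: float
    p_E_R: float

    def __post_init__(self) -> None:
        for name in ("p_A_C", "p_H_C", "p_H_R", "p_E_R"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def metabolic_demand(mass: float, coeff: float, expo: float) -> float:
    """Field metabolic rate ``coeff * mass**expo`` in kJ per day."""
    if not mass > 0:
        raise ValueError(f"mass must be > 0, got {mass}")
    return coeff * mass ** expo


def predation_rate(
    metdemand: float, preypref: float, prey_mass: float, prey_energy: float
) -> float:
    """Prey individuals consumed per predator per day.

    The fraction ``preypref`` of the predator's daily demand (kJ/day) is met
    by this prey stage; one prey individual supplies
    ``prey_mass * prey_energy`` kJ.
    """
    if not (prey_mass > 0 and prey_energy > 0):
        raise ValueError(
            f"prey mass and energy density must be > 0, got "
            f"mass={prey_mass}, energy={prey_energy}"
        )
    if not 0.0 <= preypref <= 1.0:
        raise ValueError(f"preypref must lie in [0, 1], got {preypref}")
    return metdemand * preypref / (prey_mass * prey_energy)


def compute_rates(e: EnergeticsParams) -> PredationRates:
    """All four stage-specific predation rates at the given energetics."""
    md_C = e.metdemand_C
    md_R = e.metdemand_R
    return PredationRates(
        p_A_C=predation_rate(md_C, e.preypref_A_C, e.mass_A, e.energy_A),
        p_H_C=predation_rate(md_C, e.preypref_H_C, e.mass_H, e.energy_H),
        p_H_R=predation_rate(md_R, e.preypref_H_R, e.mass_H, e.energy_H),
        p_E_R=predation_rate(md_R, e.preypref_E_R, e.mass_E, e.energy_E),
    )
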