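"""Recovery-biomarker arithmetic: urine and energy-balance conversions.

24-hr urinary excretion is converted to intake using the fractions of consumed
nitrogen (81%), potassium (80%) and sodium (86%) excreted in urine; dietary
protein is nitrogen / 0.16; biomarker energy intake is total energy
expenditure (from doubly labeled water) plus the daily change in energy
stores, valuing body-weight change at 2380 kcal/kg. Computing TEE itself from
raw isotope enrichments is out of scope — TEE is taken as an input number.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BiomarkerConstants",
    "DEFAULT_CONSTANTS",
    "urine_to_intake",
    "protein_from_nitrogen",
    "ei_from_energy_balance",
]


@dataclass(frozen=True)
class BiomarkerConstants:
    nitrogen_excretion: float = 0.81
    potassium_excretion: float = 0.80
    sodium_excretion: float = 0.86
    nitrogen_share_of_protein: float = 0.16
    energy_density_kcal_per_kg: float = 2380.0

    def __post_init__(self) -> None:
        for f in (self.nitrogen_excretion, self.potassium_excretion,
                  self.sodium_excretion, self.nitrogen_share_of_protein):
            if not (0 < f <= 1):
                raise ValueError("excretion/share fractions must lie in (0, 1]")
        if self.energy_density_kcal_per_kg <= 0:
            raise ValueError("energy density must be positive")


DEFAULT_CONSTANTS = BiomarkerConstants()


def urine_to_intake(urinary_amount: float, excretion_fraction: float) -> float:
    """Intake implied by a 24-hr urinary amount and its excretion fraction."""
    if excretion_fraction <= 0 or excretion_fraction > 1:
        raise ValueError(f"excretion fraction must lie in (0, 1], got {excretion_fraction!r}")
    if urinary_amount < 0:
        raise ValueError("urinary amount must be non-negative")
    return urinary_amount / excretion_fraction


def protein_from_nitrogen(
    nitrogen_intake: float,
    nitrogen_share: float = DEFAULT_CONSTANTS.nitrogen_share_of_protein,
) -> float:
    """Protein intake (g/day) from nitrogen intake (g/day)."""
    if nitrogen_intake < 0:
        raise ValueError("nitrogen intake must be non-negative")
    return nitrogen_intake / nitrogen_share


def ei_from_energy_balance(
    tee: float,
    daily_weight_change: float,
    density: float = DEFAULT_CONSTANTS.energy_density_kcal_per_kg,
) -> float:
    """Biomarker energy intake: TEE plus the energy value of weight change.

    tee in kcal/day, daily_weight_change in kg/day (negative when losing
    weight), density in kcal/kg.
    """
    if tee <= 0:
        raise ValueError("tee must be positive")
    return tee + density * daily_weight_change
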