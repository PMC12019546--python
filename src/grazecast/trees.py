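"""Tree-stand carbon sequestration with diminishing annual increments.

A parametric saturating-exponential growth curve represents planted
stands (blue-gum plantation shelter belts, or mixed environmental
plantings): per-hectare biomass carbon approaches a maturity stock with
strictly decreasing annual increments,

    stock(age) = perturbation * max_stock * (1 - exp(-growth_rate * age)).

Annual removals are the year-on-year biomass-C increments converted to
CO2 at the molar-mass ratio 44/12. Stands are never harvested. The
multiplicative perturbation supports the ±20% sensitivity envelope on
sequestration. Soil carbon beneath trees is not accounted here, so it
is never double-counted against the pasture soil-carbon ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TreeStand",
    "stand_stock",
    "annual_removals",
    "perturb",
    "SPECIES_PROFILES",
]

C_TO_CO2 = 44.0 / 12.0

# illustrative per-ha maturity stocks and rates for temperate plantings;
# package defaults, not calibrated to any specific inventory model
SPECIES_PROFILES = {
    "plantation_bluegum": {"max_stock": 180.0, "growth_rate": 0.09},
    "environmental_planting": {"max_stock": 110.0, "growth_rate": 0.06},
}


@dataclass(frozen=True)
class TreeStand:
    species_profile: str
    area_ha: float
    plant_year: int
    max_stock: float  # Mg C/ha at maturity
    growth_rate: float  # yr^-1
    perturbation: float = 1.0

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ValueError("area_ha must be >= 0")
        if self.max_stock <= 0 or self.growth_rate <= 0:
            raise ValueError("max_stock and growth_rate must be > 0")
        if not 0.8 <= self.perturbation <= 1.2:
            raise ValueError(
                "perturbation outside the supported [0.8, 1.2] envelope"
            )

    @classmethod
    def from_profile(cls, species_profile: str, area_ha: float,
                     plant_year: int, perturbation: float = 1.0
                     ) -> "TreeStand":
        prof = SPECIES_PROFILES[species_profile]
        return cls(species_profile, area_ha, plant_year,
                   prof["max_stock"], prof["growth_rate"], perturbation)


def stand_stock(age: float, stand: TreeStand) -> float:
    """Biomass carbon stock per hectare at a given stand age, Mg C/ha."""
    if age < 0:
        raise ValueError("age must be >= 0")
    return stand.perturbation * stand.max_stock * (
        1.0 - np.exp(-stand.growth_rate * age)
    )


def annual_removals(
    stands: list[TreeStand], years: range | list[int]
) -> pd.Series:
    """Whole-program annual CO2 removals, Mg CO2e/yr (positive magnitudes).

    removal(y) = sum over stands of
        area * (stock(age_end) - stock(age_start)) * 44/12
    with age counted from the planting year; unplanted stands contribute
    zero.
    """
    years = list(years)
    out = np.zeros(len(years))
    for stand in stands:
        for i, y in enumerate(years):
            age_end = y - stand.plant_year + 1
            if age_end <= 0:
                continue
            age_start = max(0, age_end - 1)
            inc = stand_stock(age_end, stand) - stand_stock(age_start, stand)
            out[i] += stand.area_ha * inc * C_TO_CO2
    return pd.Series(out, index=years, name="removals_mg_co2e")


def perturb(stand: TreeStand, factor: float) -> TreeStand:
    """Return a copy with the growth increments scaled by (1 + factor).

    The resulting cumulative perturbation must stay inside the ±20%
    sensitivity envelope (so a -20% step may be undone by a +25%
    relative correction, but the net excursion never leaves the band).
    """
    new = stand.perturbation * (1.0 + factor)
    if not 0.8 <= new <= 1.2:
        raise ValueError(
            f"cumulative perturbation {new:.3f} outside the supported "
            "[0.8, 1.2] envelope"
        )
    return replace(stand, perturbation=new)
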