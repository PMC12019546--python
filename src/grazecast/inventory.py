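"""Annual farm greenhouse-gas inventory and net-zero accounting.

Source coverage follows national sheep/beef greenhouse accounting
practice: enteric and manure CH4, direct and indirect N2O (fertiliser,
excreta, leaching, volatilisation), energy CO2 (diesel, electricity)
and pre-farm embedded CO2e (fertiliser, purchased feed). Gases convert
to CO2-equivalents with 100-year global warming potentials (CH4 = 28,
N2O = 265). Soil and tree sequestration are ledgered as positive
magnitudes and subtracted: net = gross - soil - trees; a year of soil
carbon loss adds to net symmetrically. Net-zero is defined on the
20-year mean of annual net emissions after discarding a 6-year spin-up.
Emissions intensity allocates net emissions between meat and wool by
protein mass.

Default emission factors are configuration values indicative of the
Australian national inventory method; override them per enterprise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GwpSet",
    "EmissionFactors",
    "EmissionsInventory",
    "NetPosition",
    "enteric_ch4",
    "manure_ch4",
    "n2o_emissions",
    "energy_and_embedded_co2e",
    "to_co2e",
    "assemble_inventory",
    "net_position",
    "emissions_intensity",
]

N2O_N_TO_N2O = 44.0 / 28.0


@dataclass(frozen=True)
class GwpSet:
    ch4: float = 28.0
    n2o: float = 265.0
    co2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ch4, self.n2o, self.co2) <= 0:
            raise ValueError("GWP values must be > 0")

    def factor(self, gas: str) -> float:
        try:
            return getattr(self, gas)
        except AttributeError:
            raise KeyError(f"unknown gas label: {gas!r}") from None


@dataclass(frozen=True)
class EmissionFactors:
    """Inventory emission factors (config; defaults are indicative only)."""

    enteric_kg_ch4_per_kg_dmi: dict[str, float] = field(
        default_factory=lambda: {"cattle": 0.0204, "sheep": 0.0188}
    )
    manure_kg_ch4_per_kg_dm_excreted: float = 0.0008  # temperate grazing
    digestibility: float = 0.70
    ef_fertiliser_n2o_n: float = 0.01  # kg N2O-N per kg N applied
    ef_excreta_n2o_n: float = 0.004  # kg N2O-N per kg N excreted
    frac_leach: float = 0.24
    ef_leach_n2o_n: float = 0.011
    frac_volat: float = 0.15
    ef_volat_n2o_n: float = 0.01
    diesel_kg_co2e_per_l: float = 2.70
    electricity_kg_co2e_per_kwh: float = 0.20
    fertiliser_embedded_kg_co2e_per_kg_n: float = 3.0
    feed_embedded_kg_co2e_per_kg_dm: float = 0.30

    def __post_init__(self) -> None:
        for name in ("manure_kg_ch4_per_kg_dm_excreted",
                     "ef_fertiliser_n2o_n", "ef_excreta_n2o_n",
                     "ef_leach_n2o_n", "ef_volat_n2o_n",
                     "diesel_kg_co2e_per_l", "electricity_kg_co2e_per_kwh",
                     "fertiliser_embedded_kg_co2e_per_kg_n",
                     "feed_embedded_kg_co2e_per_kg_dm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_leach", "frac_volat", "digestibility"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class EmissionsInventory:
    """One year's gas-by-source line items plus the sequestration ledger."""

    line_items: pd.DataFrame  # columns: source, gas, mass_mg, co2e_mg
    soil_sequestration_mg_co2e: float  # positive = accrual
    tree_sequestration_mg_co2e: float  # positive magnitude

    @property
    def gross_co2e(self) -> float:
        return float(self.line_items["co2e_mg"].sum())

    @property
    def net_co2e(self) -> float:
        return (self.gross_co2e - self.soil_sequestration_mg_co2e
                - self.tree_sequestration_mg_co2e)


@dataclass(frozen=True)
class NetPosition:
    horizon: str
    annual_net: pd.Series  # Mg CO2e/yr over the analysis window
    mean_net: float
    tolerance: float = 1.0

    @property
    def is_net_zero(self) -> bool:
        return abs(self.mean_net) <= self.tolerance

    @property
    def is_net_negative(self) -> bool:
        return self.mean_net < -self.tolerance

    @property
    def is_net_positive(self) -> bool:
        return self.mean_net > self.tolerance


def enteric_ch4(
    dmi_mg_per_class: dict[str, float],
    ef_per_class: dict[str, float],
    inhibition: float = 0.0,
) -> float:
    """Enteric methane, Mg CH4/yr.

    ``dmi_mg_per_class``: annual dry-matter intake per class (Mg DM);
    ``ef_per_class``: kg CH4 per kg DMI. ``inhibition`` is the fraction
    of enteric CH4 suppressed (feed additive / vaccine), applied
    linearly.
    """
    if not 0 <= inhibition <= 1:
        raise ValueError("inhibition must be in [0, 1]")
    total = 0.0
    for cls, dmi in dmi_mg_per_class.items():
        ef = ef_per_class[cls]
        if ef <= 0:
            raise ValueError(f"emission factor for {cls!r} must be > 0")
        total += dmi * ef
    return total * (1.0 - inhibition)


def manure_ch4(excreted_dm_mg: float, ef_manure: float) -> float:
    """Manure methane from pasture-deposited excreta, Mg CH4/yr."""
    if excreted_dm_mg < 0 or ef_manure < 0:
        raise ValueError("excreted DM and manure EF must be >= 0")
    return excreted_dm_mg * ef_manure


def n2o_emissions(
    n_fert_kg: float,
    n_excreted_kg: float,
    ef_fert: float,
    ef_excreta: float,
    frac_leach: float,
    ef_leach: float,
    frac_volat: float,
    ef_volat: float,
) -> tuple[float, float]:
    """Direct and indirect N2O, Mg N2O/yr.

    Direct emissions apply per-stream factors to applied and excreted N;
    indirect emissions route the leached and volatilised shares of both
    streams through their own factors. N2O-N converts to N2O by 44/28.
    """
    for name, v in (("frac_leach", frac_leach), ("frac_volat", frac_volat)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if min(n_fert_kg, n_excreted_kg) < 0:
        raise ValueError("N inputs must be >= 0")
    n_total = n_fert_kg + n_excreted_kg
    direct_n = n_fert_kg * ef_fert + n_excreted_kg * ef_excreta
    indirect_n = (n_total * frac_leach * ef_leach
                  + n_total * frac_volat * ef_volat)
    return (direct_n * N2O_N_TO_N2O / 1000.0,
            indirect_n * N2O_N_TO_N2O / 1000.0)


def energy_and_embedded_co2e(
    diesel_l: float,
    electricity_kwh: float,
    fertiliser_n_kg: float,
    purchased_feed_mg: float,
    ef: EmissionFactors,
) -> tuple[float, float]:
    """(energy CO2, embedded pre-farm CO2e), Mg/yr."""
    if min(diesel_l, electricity_kwh, fertiliser_n_kg,
           purchased_feed_mg) < 0:
        raise ValueError("use quantities must be >= 0")
    energy = (diesel_l * ef.diesel_kg_co2e_per_l
              + electricity_kwh * ef.electricity_kg_co2e_per_kwh) / 1000.0
    embedded = (
        fertiliser_n_kg * ef.fertiliser_embedded_kg_co2e_per_kg_n / 1000.0
        + purchased_feed_mg * ef.feed_embedded_kg_co2e_per_kg_dm
    )
    return energy, embedded


def to_co2e(mass_mg: float, gas: str, gwp: GwpSet | None = None) -> float:
    """Convert a gas mass (Mg) to Mg CO2-equivalents by its GWP100."""
    gwp = gwp or GwpSet()
    return mass_mg * gwp.factor(gas)


def assemble_inventory(
    gas_masses: dict[str, tuple[str, float]],
    soil_delta_soc_mg_co2e: float,
    tree_removals_mg_co2e: float,
    gwp: GwpSet | None = None,
) -> EmissionsInventory:
    """Build one year's inventory from source line items.

    ``gas_masses`` maps source label -> (gas, Mg gas). Soil sequestration
    is the year's SOC change expressed in CO2e (positive = accrual; a
    negative value, i.e. SOC loss, adds to net emissions); tree removals
    are positive magnitudes.
    """
    gwp = gwp or GwpSet()
    rows = [
        (source, gas, mass, to_co2e(mass, gas, gwp))
        for source, (gas, mass) in gas_masses.items()
    ]
    df = pd.DataFrame(rows, columns=["source", "gas", "mass_mg", "co2e_mg"])
    return EmissionsInventory(
        line_items=df,
        soil_sequestration_mg_co2e=soil_delta_soc_mg_co2e,
        tree_sequestration_mg_co2e=tree_removals_mg_co2e,
    )


def net_position(
    annual_net: pd.Series,
    horizon: str = "historical",
    spin_up_years: int = 6,
    window_years: int = 20,
    tolerance: float = 1.0,
) -> NetPosition:
    """Net-zero determination over the post-spin-up analysis window.

    Requires at least spin_up + window years; the first ``spin_up_years``
    are discarded and the mean taken over the next ``window_years``.
    """
    needed = spin_up_years + window_years
    if len(annual_net) < needed:
        raise ValueError(
            f"need at least {needed} years of annual net emissions, "
            f"got {len(annual_net)}"
        )
    window = annual_net.iloc[spin_up_years:spin_up_years + window_years]
    return NetPosition(
        horizon=horizon,
        annual_net=window,
        mean_net=float(window.mean()),
        tolerance=tolerance,
    )


def emissions_intensity(
    net_mg_co2e: float,
    meat_mg: float,
    wool_mg: float,
    meat_protein_fraction: float = 0.18,
    wool_protein_fraction: float = 0.60,
) -> dict[str, float]:
    """Per-product emissions intensity with protein-mass allocation.

    Each product's share of net emissions is its protein mass over the
    total protein mass; intensity is that share divided by product mass
    (Mg CO2e per Mg product).
    """
    protein = {
        "meat": meat_mg * meat_protein_fraction,
        "wool": wool_mg * wool_protein_fraction,
    }
    total = sum(protein.values())
    if total <= 0:
        raise ValueError(
            "emissions intensity undefined: no product protein mass"
        )
    masses = {"meat": meat_mg, "wool": wool_mg}
    return {
        prod: (protein[prod] / total) * net_mg_co2e / masses[prod]
        for prod in protein if masses[prod] > 0
    }
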