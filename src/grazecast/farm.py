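"""Synthetic farm-production generator.

Stands in for a daily pasture/livestock simulator: produces monthly
pasture growth, livestock dry-matter intake, supplementary feed, product
output (liveweight, greasy wool), nitrogen flows and carbon returns
(dung, litter, root residue by soil layer) with the seasonal and climate
sensitivity the downstream soil-carbon and inventory models assume.

Livestock energetics are deliberately reduced to (intake demand, product
output, feed-conversion-efficiency multiplier). Raising the FCE
multiplier lowers intake at fixed product output — the mechanism by
which feed-conversion gains mitigate enteric methane downstream.

Pasture growth is a multiplicative limitation model:

    growth = max_rate * f_T(tmean) * f_W(rain, pan_evap) * f_CO2(co2) * days

with f_T a piecewise-linear hat between cardinal temperatures, f_W the
ratio of rain to a sensitivity-scaled pan evaporation (capped at 1), and
f_CO2 = 1 + beta * ln(co2 / 350) a logarithmic CO2 fertilisation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PastureParams",
    "AnimalClass",
    "FarmConfig",
    "FarmYear",
    "pasture_growth",
    "simulate_farm_year",
    "carbon_inputs",
    "beef_farm",
    "sheep_farm",
    "beef_site_statistics",
    "sheep_site_statistics",
]

DAYS_IN_MONTH = np.array(
    [31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
)


@dataclass(frozen=True)
class PastureParams:
    """Pasture growth-response parameters.

    Cardinal temperatures (°C) define the hat function f_T: zero at or
    below t_base and at or above t_ceil, one on [t_opt_lo, t_opt_hi].
    """

    max_growth: float = 55.0  # kg DM/ha/day at no limitation
    t_base: float = 3.0
    t_opt_lo: float = 15.0
    t_opt_hi: float = 22.0
    t_ceil: float = 35.0
    water_sensitivity: float = 0.8  # f_W = min(1, rain/(w_sens*evap))
    co2_beta: float = 0.06  # f_CO2 = 1 + beta*ln(co2/350)
    root_shoot: float = 0.45  # root-derived C input per unit shoot NPP
    root_fraction_by_layer: tuple[float, ...] = (0.8, 0.2)  # 0-30, 30-100 cm
    legume_fraction: float = 0.2
    utilisation: float = 0.55  # fraction of standing growth grazeable
    litter_fraction: float = 0.35  # share of ungrazed residue becoming litter

    def __post_init__(self) -> None:
        if min(self.max_growth, self.water_sensitivity) < 0:
            raise ValueError("pasture rate parameters must be >= 0")
        if self.co2_beta < 0:
            raise ValueError("co2_beta must be >= 0")
        if not 0 <= self.legume_fraction <= 1:
            raise ValueError("legume_fraction must be in [0, 1]")
        if sum(self.root_fraction_by_layer) > 1 + 1e-12:
            raise ValueError("root fractions over layers must sum to <= 1")
        if not (self.t_base <= self.t_opt_lo <= self.t_opt_hi <= self.t_ceil):
            raise ValueError("cardinal temperatures must be ordered")


@dataclass(frozen=True)
class AnimalClass:
    label: str
    head: float
    liveweight_kg: float
    intake_kg_dm_day: float  # per head
    product: str = "none"  # meat | wool | none
    product_kg_head_yr: float = 0.0
    n_excretion_kg_head_yr: float = 0.0
    species: str = "cattle"  # cattle | sheep (enteric EF lookup key)

    def __post_init__(self) -> None:
        if min(self.head, self.liveweight_kg, self.intake_kg_dm_day,
               self.product_kg_head_yr, self.n_excretion_kg_head_yr) < 0:
            raise ValueError(f"negative rate in animal class {self.label!r}")
        if self.product not in ("meat", "wool", "none"):
            raise ValueError(f"unknown product {self.product!r}")


@dataclass(frozen=True)
class FarmConfig:
    farm_id: str
    grazed_area_ha: float
    animal_classes: tuple[AnimalClass, ...]
    pasture: PastureParams = field(default_factory=PastureParams)
    fertiliser_n_kg_ha_yr: float = 0.0
    diesel_l_yr: float = 0.0
    electricity_kwh_yr: float = 0.0
    purchased_feed_base_mg_yr: float = 0.0
    meat_protein_fraction: float = 0.18
    wool_protein_fraction: float = 0.60
    fce_multiplier: float = 1.0  # >1 lowers intake at fixed output
    product_multiplier: float = 1.0  # scales product output (e.g. biochar)
    growth_multiplier: float = 1.0  # scales pasture growth (e.g. fertility)

    def __post_init__(self) -> None:
        if self.grazed_area_ha < 0:
            raise ValueError("grazed_area_ha must be >= 0")
        if self.fce_multiplier <= 0:
            raise ValueError("fce_multiplier must be > 0")
        bad = [
            name for name in ("fertiliser_n_kg_ha_yr", "diesel_l_yr",
                              "electricity_kwh_yr",
                              "purchased_feed_base_mg_yr")
            if getattr(self, name) < 0
        ]
        if bad:
            raise ValueError(f"negative config fields: {', '.join(bad)}")


@dataclass(frozen=True)
class FarmYear:
    """One simulated production year.

    Monthly arrays have 12 entries (Jan..Dec). Carbon returns are per
    grazed hectare, Mg C/ha/month; root C is split by soil layer.
    """

    farm_id: str
    pasture_growth_kg_ha: np.ndarray  # per month
    intake_mg: np.ndarray  # total herd intake, Mg DM per month
    supplement_mg: np.ndarray  # purchased feed, Mg DM per month
    meat_mg_lw: float  # liveweight sold, Mg/yr
    wool_mg_greasy: float  # Mg/yr
    n_applied_kg: float
    n_excreted_kg: float
    dung_c_mg_ha: np.ndarray  # per month
    litter_c_mg_ha: np.ndarray  # per month
    root_c_mg_ha_by_layer: np.ndarray  # (n_layers, 12)
    dmi_per_class_kg_day: dict[str, float] = field(default_factory=dict)
    intake_mg_by_species: dict[str, float] = field(default_factory=dict)

    @property
    def annual_intake_mg(self) -> float:
        return float(self.intake_mg.sum())

    @property
    def annual_supplement_mg(self) -> float:
        return float(self.supplement_mg.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per month per variable."""
        rows = []
        for m in range(12):
            rows.append((m + 1, "pasture_growth_kg_ha",
                         self.pasture_growth_kg_ha[m]))
            rows.append((m + 1, "intake_mg", self.intake_mg[m]))
            rows.append((m + 1, "supplement_mg", self.supplement_mg[m]))
            rows.append((m + 1, "dung_c_mg_ha", self.dung_c_mg_ha[m]))
            rows.append((m + 1, "litter_c_mg_ha", self.litter_c_mg_ha[m]))
            for i in range(self.root_c_mg_ha_by_layer.shape[0]):
                rows.append((m + 1, f"root_c_mg_ha_layer{i}",
                             self.root_c_mg_ha_by_layer[i, m]))
        return pd.DataFrame(rows, columns=["month", "variable", "value"])


def _f_temperature(tmean: float, p: PastureParams) -> float:
    if tmean <= p.t_base or tmean >= p.t_ceil:
        return 0.0
    if tmean < p.t_opt_lo:
        return (tmean - p.t_base) / (p.t_opt_lo - p.t_base)
    if tmean <= p.t_opt_hi:
        return 1.0
    return (p.t_ceil - tmean) / (p.t_ceil - p.t_opt_hi)


def _f_water(rain: float, pan_evap: float, p: PastureParams) -> float:
    if rain <= 0:
        return 0.0
    demand = p.water_sensitivity * pan_evap
    if demand <= 0:
        return 1.0
    return min(1.0, rain / demand)


def pasture_growth(
    tmean: float, rain: float, pan_evap: float, params: PastureParams,
    co2_ppm: float = 350.0, days: float = 30.4,
) -> float:
    """Monthly pasture growth, kg DM/ha."""
    f_co2 = 1.0 + params.co2_beta * np.log(co2_ppm / 350.0)
    return (
        params.max_growth
        * _f_temperature(tmean, params)
        * _f_water(rain, pan_evap, params)
        * f_co2
        * days
    )


def simulate_farm_year(
    config: FarmConfig, climate_year: pd.DataFrame, seed: int = 0,
    co2_ppm: float | None = None,
) -> FarmYear:
    """Simulate one production year from 12 monthly climate records.

    The feed balance closes every month: herd intake equals demand, met
    first from available pasture (growth x area x utilisation) and
    topped up with purchased supplement. Product output scales with head
    counts and the product multiplier; the FCE multiplier divides intake
    demand at fixed output.
    """
    if len(climate_year) != 12:
        raise ValueError("climate_year must have exactly 12 monthly records")
    if co2_ppm is None:
        co2_ppm = 350.0
    p = config.pasture
    growth = np.zeros(12)
    rows = climate_year.reset_index(drop=True)
    for m in range(12):
        growth[m] = config.growth_multiplier * pasture_growth(
            rows.loc[m, "tmean"], rows.loc[m, "rain"],
            rows.loc[m, "pan_evap"], p, co2_ppm, DAYS_IN_MONTH[m],
        )

    # monthly herd demand in Mg DM, reduced by the FCE multiplier
    demand_per_day = sum(
        ac.head * ac.intake_kg_dm_day for ac in config.animal_classes
    ) / config.fce_multiplier / 1000.0  # Mg/day
    demand = demand_per_day * DAYS_IN_MONTH

    available = growth * config.grazed_area_ha * p.utilisation / 1000.0  # Mg
    consumed = np.minimum(demand, available)
    supplement = demand - consumed
    intake = consumed + supplement  # == demand by construction

    by_species: dict[str, float] = {}
    total_head_intake = sum(
        ac.head * ac.intake_kg_dm_day for ac in config.animal_classes
    )
    for ac in config.animal_classes:
        if total_head_intake > 0:
            share = ac.head * ac.intake_kg_dm_day / total_head_intake
        else:
            share = 0.0
        by_species[ac.species] = (
            by_species.get(ac.species, 0.0) + share * float(intake.sum())
        )

    dmi_per_class = {
        ac.label: ac.intake_kg_dm_day / config.fce_multiplier
        for ac in config.animal_classes
    }

    meat = sum(
        ac.head * ac.product_kg_head_yr
        for ac in config.animal_classes if ac.product == "meat"
    ) * config.product_multiplier / 1000.0
    wool = sum(
        ac.head * ac.product_kg_head_yr
        for ac in config.animal_classes if ac.product == "wool"
    ) * config.product_multiplier / 1000.0
    n_excreted = sum(
        ac.head * ac.n_excretion_kg_head_yr for ac in config.animal_classes
    )

    dung, litter, root = carbon_inputs(
        growth_kg_ha=growth,
        consumed_mg=consumed,
        intake_mg=intake,
        area_ha=config.grazed_area_ha,
        root_shoot=p.root_shoot,
        root_fraction_by_layer=p.root_fraction_by_layer,
        litter_fraction=p.litter_fraction,
    )

    return FarmYear(
        farm_id=config.farm_id,
        pasture_growth_kg_ha=growth,
        intake_mg=intake,
        supplement_mg=supplement,
        meat_mg_lw=meat,
        wool_mg_greasy=wool,
        n_applied_kg=config.fertiliser_n_kg_ha_yr * config.grazed_area_ha,
        n_excreted_kg=n_excreted,
        dung_c_mg_ha=dung,
        litter_c_mg_ha=litter,
        root_c_mg_ha_by_layer=root,
        dmi_per_class_kg_day=dmi_per_class,
        intake_mg_by_species=by_species,
    )


def carbon_inputs(
    growth_kg_ha: np.ndarray,
    consumed_mg: np.ndarray,
    intake_mg: np.ndarray,
    area_ha: float,
    digestibility: float = 0.70,
    carbon_fraction: float = 0.40,
    root_shoot: float = 0.6,
    root_fraction_by_layer: tuple[float, ...] = (0.8, 0.2),
    litter_fraction: float = 0.35,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monthly carbon returns to soil, Mg C/ha, from one production year.

    dung C   = intake x (1 - digestibility) x carbon_fraction
    litter C = ungrazed shoot residue x litter_fraction x carbon_fraction
    root C   = shoot production x root:shoot x carbon_fraction,
               split across soil layers by the layer fractions.
    """
    if not 0 < digestibility <= 1 or not 0 < carbon_fraction < 1:
        raise ValueError(
            "digestibility and carbon_fraction must be in (0, 1]"
        )
    if sum(root_fraction_by_layer) > 1 + 1e-12:
        raise ValueError("root fractions over layers must sum to <= 1")
    growth_mg_ha = np.asarray(growth_kg_ha, dtype=float) / 1000.0
    if area_ha > 0:
        consumed_mg_ha = np.asarray(consumed_mg, dtype=float) / area_ha
        intake_mg_ha = np.asarray(intake_mg, dtype=float) / area_ha
    else:
        consumed_mg_ha = np.zeros_like(growth_mg_ha)
        intake_mg_ha = np.zeros_like(growth_mg_ha)
    dung = intake_mg_ha * (1.0 - digestibility) * carbon_fraction
    residue = np.maximum(0.0, growth_mg_ha - consumed_mg_ha)
    litter = residue * litter_fraction * carbon_fraction
    root_total = growth_mg_ha * root_shoot * carbon_fraction
    fracs = np.asarray(root_fraction_by_layer)
    root = fracs[:, None] * root_total[None, :]
    return dung, litter, root


# ---------------------------------------------------------------------------
# Shipped fixture farms — calibrated to printed magnitudes (569 ha beef herd
# around 367 breeding cows; 3170 ha sheep operation around 24,750 head), not
# claimed to reproduce the real enterprises.
# ---------------------------------------------------------------------------


def beef_farm() -> FarmConfig:
    """Beef-like fixture: self-replacing cow-calf plus trading stock."""
    return FarmConfig(
        farm_id="beef",
        grazed_area_ha=569.0,
        animal_classes=(
            AnimalClass("cows", 367, 550, 10.5, "none", 0.0, 70.0, "cattle"),
            AnimalClass("replacement_heifers", 74, 380, 8.0, "none", 0.0,
                        50.0, "cattle"),
            AnimalClass("home_bred_sale", 260, 420, 9.0, "meat", 575.0,
                        55.0, "cattle"),
            AnimalClass("purchased_weaners", 115, 400, 9.0, "meat", 600.0,
                        55.0, "cattle"),
            AnimalClass("purchased_steers", 155, 460, 9.5, "meat", 545.0,
                        60.0, "cattle"),
        ),
        fertiliser_n_kg_ha_yr=40.0,
        diesel_l_yr=18_000.0,
        electricity_kwh_yr=30_000.0,
        purchased_feed_base_mg_yr=50.0,
    )


def sheep_farm() -> FarmConfig:
    """Sheep-like fixture: Merino wool plus prime-lamb flocks."""
    drier = PastureParams(max_growth=42.0, water_sensitivity=0.58,
                          co2_beta=0.06, utilisation=0.60,
                          root_fraction_by_layer=(0.8, 0.2))
    return FarmConfig(
        farm_id="sheep",
        grazed_area_ha=3170.0,
        pasture=drier,
        animal_classes=(
            AnimalClass("merino_ewes", 5300, 55, 1.5, "wool", 4.8, 10.0,
                        "sheep"),
            AnimalClass("wethers", 7500, 55, 1.4, "wool", 5.2, 10.0,
                        "sheep"),
            AnimalClass("replacements", 5500, 40, 1.2, "wool", 4.0, 8.0,
                        "sheep"),
            AnimalClass("pl_ewes", 3450, 60, 1.6, "wool", 4.5, 10.0,
                        "sheep"),
            AnimalClass("prime_lambs", 2950, 27, 0.9, "meat", 27.0, 5.0,
                        "sheep"),
            AnimalClass("cattle_herd", 450, 480, 8.5, "meat", 300.0, 55.0,
                        "cattle"),
        ),
        fertiliser_n_kg_ha_yr=8.0,
        diesel_l_yr=45_000.0,
        electricity_kwh_yr=60_000.0,
        purchased_feed_base_mg_yr=150.0,
    )


def beef_site_statistics():
    """Climatology for the beef-like site (cool temperate, ~807 mm)."""
    from .climate import SiteStatistics

    return SiteStatistics(
        annual_rain_mean=807.0,
        annual_rain_sd=139.0,
        monthly_rain_fraction=(0.05, 0.05, 0.06, 0.08, 0.10, 0.11,
                               0.12, 0.11, 0.10, 0.09, 0.07, 0.06),
        monthly_tmean=(16.5, 16.5, 15.5, 13.5, 11.5, 9.8,
                       9.1, 9.6, 10.8, 12.2, 13.8, 15.3),
        monthly_pan_evap=(150, 125, 105, 70, 45, 32,
                          34, 45, 65, 95, 120, 145),
    )


def sheep_site_statistics():
    """Climatology for the sheep-like site (midlands, ~499 mm)."""
    from .climate import SiteStatistics

    return SiteStatistics(
        annual_rain_mean=499.0,
        annual_rain_sd=103.0,
        monthly_rain_fraction=(0.07, 0.07, 0.07, 0.08, 0.09, 0.10,
                               0.10, 0.10, 0.09, 0.09, 0.07, 0.07),
        monthly_tmean=(16.7, 16.6, 14.8, 11.9, 9.2, 7.0,
                       6.5, 7.4, 9.3, 11.3, 13.4, 15.3),
        monthly_pan_evap=(170, 140, 110, 70, 42, 28,
                          30, 42, 65, 100, 130, 160),
    )
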