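"""End-to-end scenario runner.

Chains the component models for one farm, horizon and intervention
bundle: synthesise (or load) historical monthly climate, project it to
the horizon with delta-change scaling, simulate 26 production years,
run two-layer soil carbon turnover and tree-stand sequestration, build
the annual GHG inventory, discard the 6-year spin-up, take the 20-year
mean net position, run the correlated-price Monte Carlo for operating
profit and apply the hybrid carbon tax/credit. Everything downstream of
the seed is deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import climate as cl
from . import farm as fm
from . import soil as so
from . import trees as tr
from . import inventory as inv
from . import economics as ec
from . import interventions as iv
from . import impact as imp

__all__ = [
    "RunConfig",
    "ScenarioResult",
    "baseline_scenario",
    "run_scenario",
    "compare_scenarios",
    "tree_area_for_net_zero",
    "default_scaling_factors",
    "default_soil_params",
]

C_TO_CO2 = 44.0 / 12.0


def default_scaling_factors(horizon: str) -> cl.ScalingFactorSet:
    """Shipped delta-change factor sets per horizon.

    Uniform monthly values representative of a high-emissions pathway
    for a cool temperate region: modest warming, slight drying, more
    evaporative demand, and inflated interannual rainfall variability.
    """
    if horizon == "historical":
        return cl.ScalingFactorSet.identity()
    if horizon == "2030":
        return cl.ScalingFactorSet.uniform(
            "2030", temp_delta_c=0.9, rain_factor=0.97, evap_factor=1.03,
            variability_inflation=0.05,
        )
    if horizon == "2050":
        return cl.ScalingFactorSet.uniform(
            "2050", temp_delta_c=1.9, rain_factor=0.93, evap_factor=1.07,
            variability_inflation=0.10,
        )
    raise ValueError(f"unknown horizon {horizon!r}")


def default_soil_params(clay_top: float = 30.0, clay_deep: float = 35.0,
                        soc_top: float = 60.0, soc_deep: float = 40.0
                        ) -> list[so.SoilLayerParams]:
    return [
        so.SoilLayerParams(layer="0-30cm", clay_pct=clay_top, depth_cm=30.0,
                           k=so.TOPSOIL_K, initial_soc=soc_top, iom=3.0),
        so.SoilLayerParams(layer="30-100cm", clay_pct=clay_deep,
                           depth_cm=70.0, k=so.DEEP_K,
                           initial_soc=soc_deep, iom=4.0),
    ]


@dataclass(frozen=True)
class RunConfig:
    farm: str = "beef"  # beef | sheep
    horizon: str = "2030"  # historical | 2030 | 2050
    n_years: int = 26
    spin_up_years: int = 6
    window_years: int = 20
    seed: int = 1
    mc_iterations: int = 10_000
    policy: ec.CarbonPolicy = field(default_factory=ec.CarbonPolicy)
    net_zero_tolerance: float = 1.0  # Mg CO2e/yr on the 20-yr mean

    def __post_init__(self) -> None:
        if self.farm not in ("beef", "sheep"):
            raise ValueError(f"unknown farm {self.farm!r}")
        if self.n_years < self.spin_up_years + self.window_years:
            raise ValueError(
                "n_years must cover spin-up plus analysis window"
            )

    def farm_config(self) -> fm.FarmConfig:
        return fm.beef_farm() if self.farm == "beef" else fm.sheep_farm()

    def site_statistics(self) -> cl.SiteStatistics:
        return (fm.beef_site_statistics() if self.farm == "beef"
                else fm.sheep_site_statistics())

    def cost_structure(self) -> ec.CostStructure:
        total_head = sum(
            ac.head for ac in self.farm_config().animal_classes
        )
        if self.farm == "beef":
            return ec.CostStructure(overheads=250_000.0,
                                    variable_per_head=120.0,
                                    total_head=total_head)
        return ec.CostStructure(overheads=480_000.0,
                                variable_per_head=18.0,
                                total_head=total_head)


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    horizon: str
    meat_mg_lw: float  # mean annual over the analysis window
    wool_mg_greasy: float
    supplement_mg: float
    profit: ec.ProfitDistribution  # pre-carbon-price
    net: inv.NetPosition
    account: ec.CarbonAccount
    gross_co2e: float  # mean annual over the window
    soil_sequestration_co2e: float
    tree_sequestration_co2e: float
    provenance: tuple[str, ...] = ()
    adoptability: tuple[int, ...] = ()

    @property
    def production_mg(self) -> float:
        """Total livestock product mass (liveweight + greasy wool)."""
        return self.meat_mg_lw + self.wool_mg_greasy

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "horizon": self.horizon,
            "meat_mg_lw": self.meat_mg_lw,
            "wool_mg_greasy": self.wool_mg_greasy,
            "supplement_mg": self.supplement_mg,
            "profit": self.profit.summary(),
            "mean_net_mg_co2e": self.net.mean_net,
            "is_net_zero": self.net.is_net_zero,
            "is_net_negative": self.net.is_net_negative,
            "tax": self.account.tax,
            "credit_income": self.account.credit_income,
            "post_account_profit": self.account.post_account_profit,
            "gross_co2e": self.gross_co2e,
            "soil_sequestration_co2e": self.soil_sequestration_co2e,
            "tree_sequestration_co2e": self.tree_sequestration_co2e,
            "provenance": list(self.provenance),
        }


def baseline_scenario(config: RunConfig) -> iv.Scenario:
    """The fully resolved baseline parameter tree for one run config."""
    fc = config.farm_config()
    p = fc.pasture
    top, deep = p.root_fraction_by_layer
    return iv.Scenario(params={
        "farm": {
            "fce_multiplier": fc.fce_multiplier,
            "product_multiplier": fc.product_multiplier,
            "growth_multiplier": fc.growth_multiplier,
            "legume_fraction": p.legume_fraction,
            "root_fraction_top": top,
            "root_fraction_deep": deep,
            "head_multiplier": 1.0,
            "extra_area_ha": 0.0,
            "extra_area_growth_scale": 0.6,
        },
        "inventory": {
            "enteric_inhibition": 0.0,
            "enteric_ef_scale": 1.0,
        },
        "trees": {"stands": [], "perturbation": 0.0},
        "economics": {"capex": 0.0, "annual_cost_delta": 0.0,
                      "annual_income_delta": 0.0},
    })


def _effective_farm_config(config: RunConfig,
                           scenario: iv.Scenario) -> fm.FarmConfig:
    fc = config.farm_config()
    fp = scenario.params["farm"]
    top, deep = fp["root_fraction_top"], fp["root_fraction_deep"]
    total = min(1.0, top + deep)
    deep = min(deep, total)
    top = total - deep
    pasture = replace(
        fc.pasture,
        legume_fraction=min(1.0, fp["legume_fraction"]),
        root_fraction_by_layer=(top, deep),
    )
    heads = tuple(
        replace(ac, head=ac.head * fp["head_multiplier"])
        for ac in fc.animal_classes
    )
    # purchased out-of-district land contributes extra (lower-productivity)
    # grazeable area, expressed as an area equivalent
    area = (fc.grazed_area_ha
            + fp["extra_area_ha"] * fp["extra_area_growth_scale"])
    return replace(
        fc,
        grazed_area_ha=area,
        animal_classes=heads,
        pasture=pasture,
        fce_multiplier=fp["fce_multiplier"],
        product_multiplier=fp["product_multiplier"],
        growth_multiplier=fp["growth_multiplier"],
    )


def _stands_from_scenario(scenario: iv.Scenario,
                          first_year: int) -> list[tr.TreeStand]:
    tp = scenario.params["trees"]
    stands = []
    for spec in tp["stands"]:
        stand = tr.TreeStand.from_profile(
            spec["species_profile"], spec["area_ha"],
            first_year + spec.get("plant_year_offset", 0),
        )
        pert = tp.get("perturbation", 0.0)
        if pert:
            stand = tr.perturb(stand, pert)
        stands.append(stand)
    return stands


def run_scenario(
    config: RunConfig,
    bundle: str | None = None,
    scenario: iv.Scenario | None = None,
    independent_inhibition: bool = False,
) -> ScenarioResult:
    """Run one scenario end to end.

    ``bundle`` names a catalog theme (or None / "BASE" for the
    baseline); alternatively pass a pre-built ``scenario``.
    """
    if scenario is None:
        scenario = baseline_scenario(config)
        label = bundle or "BASE"
        adopt: tuple[int, ...] = ()
        if bundle and bundle != "BASE":
            items = iv.catalog(bundle, config.farm, config.horizon)
            scenario = iv.stack(items, scenario,
                                independent_inhibition=independent_inhibition)
            adopt = tuple(item.adoptability for item in items)
    else:
        label = bundle or "+".join(scenario.provenance) or "custom"
        adopt = ()

    # --- climate -----------------------------------------------------------
    hist = cl.synth_historical(
        config.site_statistics(), config.n_years, seed=config.seed,
    )
    factors = default_scaling_factors(config.horizon)
    series = cl.apply_scaling(hist, factors, seed=config.seed + 1)

    # --- farm production ---------------------------------------------------
    eff = _effective_farm_config(config, scenario)
    years = series.year_blocks()
    farm_years = [
        fm.simulate_farm_year(eff, yr, seed=config.seed,
                              co2_ppm=series.co2_ppm)
        for yr in years
    ]

    # --- soil carbon (per grazed ha, both layers) --------------------------
    soil_params = default_soil_params()
    n_months = len(series.records)
    plant_c = np.zeros((2, n_months))
    dung_c = np.zeros(n_months)
    for yi, fy in enumerate(farm_years):
        sl = slice(yi * 12, yi * 12 + 12)
        plant_c[0, sl] = fy.litter_c_mg_ha + fy.root_c_mg_ha_by_layer[0]
        plant_c[1, sl] = fy.root_c_mg_ha_by_layer[1]
        dung_c[sl] = fy.dung_c_mg_ha
    soil = so.run_soil_carbon(series.records, plant_c, dung_c, soil_params)
    annual_dsoc = (
        soil.groupby("year")["delta_soc_mg_ha"].sum()
    )  # Mg C/ha/yr summed over layers
    soil_co2e = annual_dsoc * eff.grazed_area_ha * C_TO_CO2

    # --- trees -------------------------------------------------------------
    first_year = int(series.records["year"].min())
    stands = _stands_from_scenario(scenario, first_year)
    year_list = sorted(annual_dsoc.index)
    removals = tr.annual_removals(stands, year_list)

    # --- annual GHG inventory ----------------------------------------------
    ef = inv.EmissionFactors()
    ef_scale = scenario.get("inventory.enteric_ef_scale")
    inhibition = scenario.get("inventory.enteric_inhibition")
    annual_net = []
    gross_list, soil_list, tree_list = [], [], []
    for yi, fy in enumerate(farm_years):
        y = year_list[yi]
        dmi_by_species = fy.intake_mg_by_species
        enteric = inv.enteric_ch4(
            dmi_by_species,
            {sp: ef.enteric_kg_ch4_per_kg_dmi[sp] * ef_scale
             for sp in dmi_by_species},
            inhibition,
        )
        excreted_dm = fy.annual_intake_mg * (1.0 - ef.digestibility)
        manure = inv.manure_ch4(excreted_dm,
                                ef.manure_kg_ch4_per_kg_dm_excreted)
        direct, indirect = inv.n2o_emissions(
            fy.n_applied_kg, fy.n_excreted_kg,
            ef.ef_fertiliser_n2o_n, ef.ef_excreta_n2o_n,
            ef.frac_leach, ef.ef_leach_n2o_n,
            ef.frac_volat, ef.ef_volat_n2o_n,
        )
        energy, embedded = inv.energy_and_embedded_co2e(
            eff.diesel_l_yr, eff.electricity_kwh_yr,
            fy.n_applied_kg,
            eff.purchased_feed_base_mg_yr + fy.annual_supplement_mg,
            ef,
        )
        inventory = inv.assemble_inventory(
            {
                "enteric_ch4": ("ch4", enteric),
                "manure_ch4": ("ch4", manure),
                "direct_n2o": ("n2o", direct),
                "indirect_n2o": ("n2o", indirect),
                "energy_co2": ("co2", energy),
                "embedded_co2e": ("co2", embedded),
            },
            soil_delta_soc_mg_co2e=float(soil_co2e.loc[y]),
            tree_removals_mg_co2e=float(removals.loc[y]),
        )
        annual_net.append(inventory.net_co2e)
        gross_list.append(inventory.gross_co2e)
        soil_list.append(inventory.soil_sequestration_mg_co2e)
        tree_list.append(inventory.tree_sequestration_mg_co2e)

    net_series = pd.Series(annual_net, index=year_list)
    net = inv.net_position(
        net_series, config.horizon, config.spin_up_years,
        config.window_years, config.net_zero_tolerance,
    )

    # --- economics ---------------------------------------------------------
    win = slice(config.spin_up_years,
                config.spin_up_years + config.window_years)
    meat = float(np.mean([fy.meat_mg_lw for fy in farm_years[win]]))
    wool = float(np.mean([fy.wool_mg_greasy for fy in farm_years[win]]))
    suppl = float(np.mean(
        [fy.annual_supplement_mg for fy in farm_years[win]]
    ))
    econ = scenario.params["economics"]
    costs = replace(
        config.cost_structure(),
        capex=econ["capex"],
        annual_cost_delta=econ["annual_cost_delta"],
        annual_income_delta=econ["annual_income_delta"],
        total_head=sum(ac.head for ac in eff.animal_classes),
    )
    profit = ec.monte_carlo_profit(
        meat, wool, suppl, ec.default_price_model(), costs,
        n=config.mc_iterations, seed=config.seed + 2,
    )
    account = ec.carbon_account(net, config.policy, profit.mean)

    w = range(config.spin_up_years,
              config.spin_up_years + config.window_years)
    return ScenarioResult(
        label=label,
        horizon=config.horizon,
        meat_mg_lw=meat,
        wool_mg_greasy=wool,
        supplement_mg=suppl,
        profit=profit,
        net=net,
        account=account,
        gross_co2e=float(np.mean([gross_list[i] for i in w])),
        soil_sequestration_co2e=float(np.mean([soil_list[i] for i in w])),
        tree_sequestration_co2e=float(np.mean([tree_list[i] for i in w])),
        provenance=scenario.provenance,
        adoptability=adopt,
    )


def compare_scenarios(results: list[ScenarioResult]) -> dict:
    """Set-wise comparison report: impact scores, MACC, carbon ledger."""
    horizons = {r.horizon for r in results}
    if len(horizons) > 1:
        raise ValueError(
            f"cannot compare across horizons: {sorted(horizons)}"
        )
    scores = imp.normalize_scores([
        (r.label, r.production_mg, r.profit.mean, r.net.mean_net)
        for r in results
    ])
    base = next((r for r in results if r.label == "BASE"), results[0])
    others = [r for r in results if r is not base]
    curve, zero, increasing = ec.macc(
        base.net.mean_net, base.profit.mean,
        [(r.label, r.net.mean_net, r.profit.mean) for r in others],
    )
    ledger = pd.DataFrame([
        {
            "scenario": r.label,
            "pre_tax_profit": r.profit.mean,
            "mean_net_mg_co2e": r.net.mean_net,
            "carbon_tax": r.account.tax,
            "credit_income": r.account.credit_income,
            "post_account_profit": r.account.post_account_profit,
        }
        for r in results
    ])
    return {"scores": scores, "macc": curve,
            "zero_abatement": zero, "emission_increasing": increasing,
            "ledger": ledger}


def tree_area_for_net_zero(
    config: RunConfig,
    inhibition: float,
    species_profile: str | None = None,
    tree_perturbation: float = 0.0,
    area_bounds: tuple[float, float] = (0.0, 2000.0),
    tol_mg: float = 1.0,
    max_iter: int = 60,
) -> tuple[float, ScenarioResult]:
    """Bisect on planted area until the 20-year mean net is ~zero.

    Returns (area_ha, result at that area). Raises if even the upper
    bound cannot reach net-zero.
    """
    if species_profile is None:
        species_profile = ("plantation_bluegum" if config.farm == "beef"
                           else "environmental_planting")

    def run_at(area: float) -> ScenarioResult:
        scenario = baseline_scenario(config)
        params = copy.deepcopy(scenario.params)
        params["inventory"]["enteric_inhibition"] = inhibition
        params["trees"]["perturbation"] = tree_perturbation
        if area > 0:
            params["trees"]["stands"].append(
                {"species_profile": species_profile, "area_ha": area,
                 "plant_year_offset": 0}
            )
        return run_scenario(
            config, bundle=f"inh{inhibition:.2f}_area{area:.1f}",
            scenario=iv.Scenario(params=params,
                                 provenance=scenario.provenance),
        )

    lo, hi = area_bounds
    r_lo, r_hi = run_at(lo), run_at(hi)
    if r_lo.net.mean_net < -tol_mg:
        return lo, r_lo
    if r_hi.net.mean_net > tol_mg:
        raise ValueError(
            f"net-zero unreachable: mean net at {hi} ha is still "
            f"{r_hi.net.mean_net:.1f} Mg CO2e/yr"
        )
    result = r_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = run_at(mid)
        if abs(r_mid.net.mean_net) <= tol_mg:
            return mid, r_mid
        if r_mid.net.mean_net > 0:
            lo = mid
        else:
            hi, result = mid, r_mid
    return hi, result
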