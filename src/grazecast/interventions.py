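"""Composable intervention algebra and the shipped adaptation catalog.

An intervention is a declarative set of parameter modifications
(multiply / add / set on a dotted path into the scenario parameter
tree) plus economic deltas (capital expenditure, annual cost and income
changes), optional tree plantings, an optional enteric-methane
inhibition fraction, and an adoptability score (an input attribute
elicited elsewhere, carried through unchanged).

Bundles stack interventions onto a baseline scenario by a left fold of
``apply``. Multiplicative modifications commute; set-mode modifications
are order-sensitive and a repeated set on the same path is recorded as
a provenance warning. Enteric inhibitions from several interventions in
one stack compose conservatively by default — the maximum single
fraction (a feed additive and a vaccine both act on the same rumen
methanogenesis, so their effects are not assumed independent) — with an
independent-action mode 1 - prod(1 - f_i) available behind a flag.

The shipped catalog mirrors the published adaptation themes: Low
Hanging Fruit (LHF), Towards Carbon Neutral (TCN), Income
Diversification (ID) and the Carbon Neutral packages CN1-CN4, for a
beef and a sheep enterprise at the 2030 and 2050 horizons. Items whose
biophysical detail lives in a proprietary pasture simulator (calendar
shifts, soil fertility, pasture renovation) are encoded as direct
production/cost levers and flagged as stand-ins in the catalog
docstrings.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

__all__ = [
    "Modification",
    "Intervention",
    "Scenario",
    "apply",
    "stack",
    "catalog",
    "combine_inhibitions",
    "THEMES",
]

THEMES = ("LHF", "TCN", "ID", "ASP", "ASP_PT", "CN1", "CN2", "CN3", "CN4")


class PathError(KeyError):
    """A modification path does not resolve against the scenario schema."""


class CompositionError(ValueError):
    """Conflicting set-mode modifications in one stack."""


@dataclass(frozen=True)
class Modification:
    path: str  # dotted path into the scenario parameter tree
    mode: str  # multiply | add | set
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("multiply", "add", "set"):
            raise ValueError(f"unknown modification mode {self.mode!r}")
        if self.mode == "multiply" and self.value <= 0:
            raise ValueError("multiply values must be > 0")


@dataclass(frozen=True)
class Intervention:
    name: str
    modifications: tuple[Modification, ...] = ()
    capex: float = 0.0
    annual_cost_delta: float = 0.0
    annual_income_delta: float = 0.0
    adoptability: int = 3  # ordinal 1-5, pass-through input attribute
    tags: tuple[str, ...] = ()
    enteric_inhibition: float | None = None  # fraction of enteric CH4 cut
    plantings: tuple[dict, ...] = ()  # tree stand specs to append

    def __post_init__(self) -> None:
        if not 1 <= self.adoptability <= 5:
            raise ValueError("adoptability must be an ordinal in 1..5")
        if self.enteric_inhibition is not None and not (
            0 <= self.enteric_inhibition <= 1
        ):
            raise ValueError("enteric_inhibition must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A fully resolved parameter tree plus application provenance."""

    params: dict
    provenance: tuple[str, ...] = ()

    def get(self, path: str) -> float:
        node = self.params
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                raise PathError(f"unresolvable parameter path: {path!r}")
            node = node[part]
        return node


def _set_path(params: dict, path: str, value) -> None:
    parts = path.split(".")
    node = params
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise PathError(f"unresolvable parameter path: {path!r}")
        node = node[part]
    if parts[-1] not in node:
        raise PathError(f"unresolvable parameter path: {path!r}")
    node[parts[-1]] = value


def combine_inhibitions(fractions: list[float],
                        independent: bool = False) -> float:
    """Compose several enteric-inhibition fractions into one.

    Default (non-independent): the maximum single fraction. Independent
    action: 1 - prod(1 - f_i). Either way the result never exceeds 1.
    """
    if not fractions:
        return 0.0
    if independent:
        p = 1.0
        for f in fractions:
            p *= 1.0 - f
        return min(1.0, 1.0 - p)
    return min(1.0, max(fractions))


def apply(intervention: Intervention, scenario: Scenario) -> Scenario:
    """Apply one intervention, returning a modified copy.

    Never mutates its input. A set-mode modification on a path that an
    earlier intervention already set is applied but recorded as a
    warning entry in provenance.
    """
    params = copy.deepcopy(scenario.params)
    prov = list(scenario.provenance)
    for mod in intervention.modifications:
        current = Scenario(params).get(mod.path)
        if mod.mode == "multiply":
            _set_path(params, mod.path, current * mod.value)
        elif mod.mode == "add":
            _set_path(params, mod.path, current + mod.value)
        else:
            already = any(
                p.startswith(f"set:{mod.path}=") for p in prov
            )
            if already:
                prov.append(
                    f"warn:set-after-set on {mod.path} by "
                    f"{intervention.name}"
                )
            _set_path(params, mod.path, mod.value)
            prov.append(f"set:{mod.path}={mod.value}")
    if intervention.enteric_inhibition is not None:
        _set_path(params, "inventory.enteric_inhibition",
                  intervention.enteric_inhibition)
    econ = params.setdefault("economics", {})
    econ["capex"] = econ.get("capex", 0.0) + intervention.capex
    econ["annual_cost_delta"] = (
        econ.get("annual_cost_delta", 0.0) + intervention.annual_cost_delta
    )
    econ["annual_income_delta"] = (
        econ.get("annual_income_delta", 0.0)
        + intervention.annual_income_delta
    )
    stands = params.setdefault("trees", {}).setdefault("stands", [])
    stands.extend(copy.deepcopy(list(intervention.plantings)))
    prov.append(intervention.name)
    return Scenario(params=params, provenance=tuple(prov))


def stack(
    interventions: list[Intervention],
    scenario: Scenario,
    independent_inhibition: bool = False,
    allow_set_conflicts: bool = False,
) -> Scenario:
    """Left-fold ``apply`` over an ordered intervention list.

    Enteric inhibitions carried by several interventions compose via
    :func:`combine_inhibitions` rather than last-wins. Conflicting
    set-mode modifications on the same path raise unless explicitly
    allowed.
    """
    set_paths: dict[str, str] = {}
    for iv in interventions:
        for mod in iv.modifications:
            if mod.mode == "set":
                if mod.path in set_paths and not allow_set_conflicts:
                    raise CompositionError(
                        f"both {set_paths[mod.path]!r} and {iv.name!r} "
                        f"set {mod.path!r}; pass allow_set_conflicts "
                        "to override"
                    )
                set_paths.setdefault(mod.path, iv.name)
    out = scenario
    for iv in interventions:
        out = apply(iv, out)
    fractions = [
        iv.enteric_inhibition for iv in interventions
        if iv.enteric_inhibition is not None
    ]
    if len(fractions) > 1:
        combined = combine_inhibitions(fractions, independent_inhibition)
        params = copy.deepcopy(out.params)
        _set_path(params, "inventory.enteric_inhibition", combined)
        out = Scenario(params=params, provenance=out.provenance)
    return out


# ---------------------------------------------------------------------------
# Shipped catalog
# ---------------------------------------------------------------------------


def _asparagopsis(farm: str) -> Intervention:
    """Red-seaweed feed additive: 80% enteric CH4 inhibition."""
    cost = 70_000.0 if farm == "beef" else 110_000.0  # stand-in supply cost
    return Intervention(
        name="asparagopsis",
        enteric_inhibition=0.80,
        annual_cost_delta=cost,
        adoptability=2,
        tags=("methane", "feed-additive"),
    )


def _vaccine() -> Intervention:
    """Anti-methanogen vaccine: 30% enteric CH4 inhibition."""
    return Intervention(
        name="methane_vaccine",
        enteric_inhibition=0.30,
        annual_cost_delta=15_000.0,
        adoptability=3,
        tags=("methane",),
    )


def _fce(horizon: str, transformational: bool) -> Intervention:
    """Feed-conversion efficiency gain: intake falls at fixed output.

    Incremental: +10% (2030) / +15% (2050); transformational: +20% /
    +30%.
    """
    if transformational:
        gain = 1.20 if horizon == "2030" else 1.30
        name, adopt, cost = "tfce", 2, 25_000.0
    else:
        gain = 1.10 if horizon == "2030" else 1.15
        name, adopt, cost = "fce", 4, 10_000.0
    return Intervention(
        name=name,
        modifications=(
            Modification("farm.fce_multiplier", "multiply", gain),
        ),
        annual_cost_delta=cost,
        adoptability=adopt,
        tags=("efficiency",),
    )


def _biochar(farm: str) -> Intervention:
    """Biochar feed supplement: +5% liveweight (beef) and -10% enteric CH4."""
    mods = [Modification("inventory.enteric_ef_scale", "multiply", 0.90)]
    if farm == "beef":
        mods.append(
            Modification("farm.product_multiplier", "multiply", 1.05)
        )
    return Intervention(
        name="biochar",
        modifications=tuple(mods),
        annual_cost_delta=12_000.0,
        adoptability=3,
        tags=("methane", "feed-additive"),
    )


def _lucerne(farm: str) -> Intervention:
    """Lucerne pasture renovation: deeper roots, more legume, more growth.

    The biophysical detail of sward renovation is reduced to these
    config-visible levers (stand-in values).
    """
    return Intervention(
        name="lucerne_renovation",
        modifications=(
            Modification("farm.growth_multiplier", "multiply", 1.08),
            Modification("farm.legume_fraction", "set", 0.35),
            Modification("farm.root_fraction_deep", "multiply", 1.5),
        ),
        capex=150_000.0 if farm == "beef" else 300_000.0,
        annual_cost_delta=5_000.0,
        adoptability=4,
        tags=("pasture", "soil-carbon"),
    )


def _trees(farm: str, area_ha: float, plant_year_offset: int = 0
           ) -> Intervention:
    """Tree planting: blue-gum plantation (beef, purchased land) or
    environmental thickening of existing non-grazed land (sheep)."""
    if farm == "beef":
        profile, capex_per_ha = "plantation_bluegum", 11_000.0
    else:
        profile, capex_per_ha = "environmental_planting", 2_500.0
    return Intervention(
        name=f"trees_{int(area_ha)}ha",
        plantings=(
            {"species_profile": profile, "area_ha": area_ha,
             "plant_year_offset": plant_year_offset},
        ),
        capex=capex_per_ha * area_ha,
        annual_cost_delta=20.0 * area_ha,
        adoptability=3,
        tags=("sequestration",),
    )


def _lhf_items(farm: str, horizon: str) -> list[Intervention]:
    calendar = Intervention(
        name="calendar_and_selling_dates",
        modifications=(
            Modification("farm.product_multiplier", "multiply", 1.02),
        ),
        adoptability=5,
        tags=("management",),
    )
    fertility = Intervention(
        name="soil_fertility",
        modifications=(
            Modification("farm.growth_multiplier", "multiply", 1.03),
        ),
        annual_cost_delta=8_000.0,
        adoptability=5,
        tags=("pasture",),
    )
    rooting = Intervention(
        name="deeper_rooting_species",
        modifications=(
            Modification("farm.root_fraction_deep", "multiply", 1.10),
        ),
        adoptability=4,
        tags=("pasture", "soil-carbon"),
    )
    return [calendar, fertility, rooting, _fce(horizon, False)]


def _id_items(farm: str) -> list[Intervention]:
    if farm == "beef":
        land = Intervention(
            name="land_purchase",
            modifications=(
                Modification("farm.extra_area_ha", "add", 300.0),
                Modification("farm.head_multiplier", "multiply", 1.15),
            ),
            capex=2_000_000.0,
            annual_cost_delta=80_000.0,
            adoptability=3,
            tags=("diversification",),
        )
        return [land]
    wind = Intervention(
        name="wind_farm_lease",
        annual_income_delta=216_000.0,  # 12 turbines, lease stand-in
        adoptability=3,
        tags=("diversification",),
    )
    grapes = Intervention(
        name="vineyard_30ha",
        capex=600_000.0,
        annual_cost_delta=40_000.0,
        annual_income_delta=130_000.0,
        adoptability=2,
        tags=("diversification",),
    )
    return [wind, grapes]


def _tree_area(theme: str, farm: str, horizon: str) -> float:
    if farm == "beef":
        if theme in ("CN2", "CN4"):
            return 55.0 if horizon == "2030" else 110.0
        return 50.0  # TCN / ASP_PT / CN1 / CN3
    if theme in ("CN2", "CN4"):
        return 220.0
    return 200.0


def catalog(theme: str, farm: str, horizon: str) -> list[Intervention]:
    """The shipped intervention list for one theme, farm and horizon.

    Themes: LHF, TCN, ID, ASP (feed additive alone), ASP_PT (additive
    plus planting), CN1 (additive + transformational FCE + trees),
    CN2 (as CN1 with the larger planting), CN3 (additive + lucerne +
    trees), CN4 (as CN3 with the larger planting).
    """
    if farm not in ("beef", "sheep") or horizon not in ("2030", "2050") \
            or theme not in THEMES:
        raise ValueError(
            f"unknown combination ({theme!r}, {farm!r}, {horizon!r}); "
            f"themes: {', '.join(THEMES)}; farms: beef, sheep; "
            "horizons: 2030, 2050"
        )
    if theme == "LHF":
        return _lhf_items(farm, horizon)
    if theme == "TCN":
        return (_lhf_items(farm, horizon)
                + [_lucerne(farm), _vaccine(),
                   _trees(farm, _tree_area("TCN", farm, horizon))])
    if theme == "ID":
        return _id_items(farm)
    if theme == "ASP":
        return [_asparagopsis(farm)]
    if theme == "ASP_PT":
        return [_asparagopsis(farm),
                _trees(farm, _tree_area("ASP_PT", farm, horizon))]
    area = _tree_area(theme, farm, horizon)
    if theme in ("CN1", "CN2"):
        return [_asparagopsis(farm), _fce(horizon, True),
                _trees(farm, area)]
    # CN3 / CN4
    return [_asparagopsis(farm), _lucerne(farm), _trees(farm, area)]
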