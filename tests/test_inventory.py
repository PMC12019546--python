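"""GHG inventory: source computations, GWP conversion, netting, net-zero
determination and protein-mass allocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grazecast.inventory import (
    EmissionFactors,
    GwpSet,
    assemble_inventory,
    emissions_intensity,
    energy_and_embedded_co2e,
    enteric_ch4,
    manure_ch4,
    n2o_emissions,
    net_position,
    to_co2e,
)


class TestGwpConversion:
    def test_methane_gwp100(self):
        assert to_co2e(1.0, "ch4") == 28.0

    def test_nitrous_oxide_gwp100(self):
        assert to_co2e(1.0, "n2o") == 265.0

    def test_zero_mass(self):
        assert to_co2e(0.0, "co2") == 0.0

    def test_unknown_gas_named_in_error(self):
        with pytest.raises(KeyError, match="sf6"):
            to_co2e(1.0, "sf6")

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, a, b):
        assert to_co2e(a + b, "ch4") == pytest.approx(
            to_co2e(a, "ch4") + to_co2e(b, "ch4")
        )


class TestEntericCh4:
    def test_full_inhibition_eliminates_emissions(self):
        assert enteric_ch4({"cattle": 1000.0}, {"cattle": 0.02}, 1.0) == 0.0

    def test_80pct_inhibition_leaves_exactly_20pct(self):
        base = enteric_ch4({"cattle": 1000.0}, {"cattle": 0.02}, 0.0)
        cut = enteric_ch4({"cattle": 1000.0}, {"cattle": 0.02}, 0.8)
        assert cut == pytest.approx(0.2 * base)

    def test_two_class_hand_sum(self):
        out = enteric_ch4(
            {"cattle": 1500.0, "sheep": 4000.0},
            {"cattle": 0.0204, "sheep": 0.0188},
        )
        assert out == pytest.approx(1500 * 0.0204 + 4000 * 0.0188,
                                    rel=1e-12)

    def test_inhibition_out_of_range(self):
        with pytest.raises(ValueError):
            enteric_ch4({"cattle": 1.0}, {"cattle": 0.02}, 1.2)

    def test_net_emissions_strictly_decrease_with_inhibition(self):
        values = [
            enteric_ch4({"cattle": 1000.0}, {"cattle": 0.02}, f)
            for f in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(values) < 0)


class TestManureAndN2o:
    def test_zero_excretion_zero_methane(self):
        assert manure_ch4(0.0, 0.0008) == 0.0

    def test_doubling_excretion_doubles_methane(self):
        assert manure_ch4(200.0, 0.0008) == pytest.approx(
            2 * manure_ch4(100.0, 0.0008)
        )

    def test_fixture_product_oracle(self):
        assert manure_ch4(1234.5, 0.0008) == pytest.approx(1234.5 * 0.0008)

    def test_no_nitrogen_no_n2o(self):
        assert n2o_emissions(0, 0, 0.01, 0.004, 0.24, 0.011, 0.15,
                             0.01) == (0.0, 0.0)

    def test_stoichiometric_conversion_44_over_28(self):
        # 28 kg of N2O-N is 44 kg of N2O: ef 1 on 28 kg N, nothing else
        direct, _ = n2o_emissions(28.0, 0.0, 1.0, 0.0, 0, 0, 0, 0)
        assert direct == pytest.approx(0.044)  # Mg

    def test_all_paths_hand_computed(self):
        n_fert, n_exc = 10_000.0, 40_000.0
        direct, indirect = n2o_emissions(
            n_fert, n_exc, 0.01, 0.004, 0.24, 0.011, 0.15, 0.01
        )
        conv = 44.0 / 28.0
        exp_direct = (10_000 * 0.01 + 40_000 * 0.004) * conv / 1000
        n_tot = 50_000.0
        exp_indirect = (n_tot * 0.24 * 0.011 + n_tot * 0.15 * 0.01) \
            * conv / 1000
        assert direct == pytest.approx(exp_direct, rel=1e-12)
        assert indirect == pytest.approx(exp_indirect, rel=1e-12)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            n2o_emissions(1, 1, 0.01, 0.004, 1.5, 0.011, 0.1, 0.01)


class TestEnergyEmbedded:
    def test_all_zero(self):
        ef = EmissionFactors()
        assert energy_and_embedded_co2e(0, 0, 0, 0, ef) == (0.0, 0.0)

    def test_single_source(self):
        ef = EmissionFactors()
        energy, _ = energy_and_embedded_co2e(1000.0, 0, 0, 0, ef)
        assert energy == pytest.approx(1000 * 2.70 / 1000)

    def test_multi_source_summation_oracle(self):
        ef = EmissionFactors()
        energy, embedded = energy_and_embedded_co2e(
            18_000, 30_000, 22_000, 150, ef
        )
        assert energy == pytest.approx(
            (18_000 * 2.70 + 30_000 * 0.20) / 1000
        )
        assert embedded == pytest.approx(22_000 * 3.0 / 1000 + 150 * 0.30)


class TestAssembleAndNetPosition:
    def test_empty_inventory_nets_zero(self):
        inv = assemble_inventory({}, 0.0, 0.0)
        assert inv.gross_co2e == 0.0 and inv.net_co2e == 0.0

    def test_sequestration_equal_to_gross_gives_net_zero(self):
        inv = assemble_inventory(
            {"enteric_ch4": ("ch4", 10.0)}, 100.0, 180.0
        )
        assert inv.gross_co2e == pytest.approx(280.0)
        assert inv.net_co2e == pytest.approx(0.0)

    def test_soc_loss_adds_to_net_symmetrically(self):
        gain = assemble_inventory({"x": ("co2", 100.0)}, 50.0, 0.0)
        loss = assemble_inventory({"x": ("co2", 100.0)}, -50.0, 0.0)
        assert gain.net_co2e == pytest.approx(50.0)
        assert loss.net_co2e == pytest.approx(150.0)

    def test_random_fixture_matches_ledger_oracle(self):
        rng = np.random.default_rng(0)
        masses = {
            f"src{i}": (gas, float(rng.uniform(0, 10)))
            for i, gas in enumerate(["ch4", "n2o", "co2", "ch4"])
        }
        gwp = {"ch4": 28.0, "n2o": 265.0, "co2": 1.0}
        expected_gross = sum(gwp[g] * m for g, m in masses.values())
        inv = assemble_inventory(masses, 12.0, 34.0)
        assert inv.gross_co2e == pytest.approx(expected_gross, rel=1e-12)
        assert inv.net_co2e == pytest.approx(expected_gross - 46.0,
                                             rel=1e-12)

    def test_additivity_of_sources(self):
        a = assemble_inventory({"one": ("ch4", 3.0)}, 0, 0)
        b = assemble_inventory({"two": ("n2o", 2.0)}, 0, 0)
        both = assemble_inventory(
            {"one": ("ch4", 3.0), "two": ("n2o", 2.0)}, 0, 0
        )
        assert both.gross_co2e == pytest.approx(a.gross_co2e + b.gross_co2e)

    def test_net_zero_flag_for_constant_zero(self):
        series = pd.Series(np.zeros(26))
        pos = net_position(series)
        assert pos.is_net_zero and not pos.is_net_negative

    def test_constant_negative_five(self):
        pos = net_position(pd.Series(np.full(26, -5.0)))
        assert pos.mean_net == pytest.approx(-5.0)
        assert pos.is_net_negative and not pos.is_net_zero

    def test_26_year_fixture_mean_over_window_only(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(100, 30, 26)
        pos = net_position(pd.Series(vals))
        assert pos.mean_net == pytest.approx(vals[6:26].mean())

    def test_insufficient_years_error_states_requirement(self):
        with pytest.raises(ValueError, match="26"):
            net_position(pd.Series(np.zeros(20)))


class TestEmissionsIntensity:
    def test_single_product_takes_full_share(self):
        out = emissions_intensity(100.0, meat_mg=10.0, wool_mg=0.0)
        assert out == {"meat": pytest.approx(10.0)}

    def test_equal_protein_masses_split_evenly(self):
        out = emissions_intensity(
            100.0, meat_mg=10.0, wool_mg=10.0,
            meat_protein_fraction=0.3, wool_protein_fraction=0.3,
        )
        assert out["meat"] == pytest.approx(out["wool"])

    def test_protein_mass_allocation_hand_example(self):
        # meat 10 Mg at 0.18, wool 2 Mg at 0.60: protein 1.8 vs 1.2
        out = emissions_intensity(
            100.0, meat_mg=10.0, wool_mg=2.0,
            meat_protein_fraction=0.18, wool_protein_fraction=0.60,
        )
        assert out["meat"] == pytest.approx(0.6 * 100 / 10)
        assert out["wool"] == pytest.approx(0.4 * 100 / 2)

    def test_no_products_is_undefined(self):
        with pytest.raises(ValueError):
            emissions_intensity(100.0, 0.0, 0.0)

    def test_invariant_to_sub_lot_splitting(self):
        # splitting meat into two lots cannot change the intensity:
        # intensity depends only on totals
        whole = emissions_intensity(90.0, 12.0, 3.0)
        halves = emissions_intensity(90.0, 6.0 + 6.0, 3.0)
        assert whole["meat"] == pytest.approx(halves["meat"])
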