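# grazecast

Costing the transition of grazing livestock farms to net-zero greenhouse-gas
emissions.

`grazecast` is a farm-systems analysis toolkit for researchers and advisors
studying how beef and sheep enterprises can reach carbon neutrality under
changing climates. It chains the standard components of a whole-farm GHG
study into one seeded, testable pipeline:

1. **Climate futures** — monthly historical weather (read from SILO-style
   CSV or synthesised from site statistics) projected to 2030/2050 horizons
   by the delta-change method, with optional inflation of interannual
   rainfall variability. Atmospheric CO₂ is 350 / 450 / 530 ppm for the
   historical / 2030 / 2050 horizons.
2. **Synthetic farm production** — a generator standing in for a daily
   pasture/livestock simulator: monthly pasture growth with temperature,
   water and CO₂ limitation, a closed feed balance (pasture + purchased
   supplement = herd demand), product output, nitrogen flows, and carbon
   returns to soil (dung, litter, root residue by depth layer). Two fixture
   farms ship with the package: a 569 ha high-rainfall beef herd and a
   3170 ha, ~24,750-head sheep operation.
3. **Soil organic carbon** — a five-pool RothC 26.3 implementation (DPM,
   RPM, BIO, HUM, IOM) run monthly per depth layer, with the standard
   temperature / moisture-deficit / cover rate modifiers and a closed-form
   steady state used as a numerical oracle. Pool decomposition follows
   Δ = P·(1 − e^(−k·a·b·c/12)); decomposed C splits CO₂ : (BIO+HUM) as
   x : 1 with x = 1.67(1.85 + 1.60 e^(−0.0786·clay)).
4. **Tree carbon** — saturating-exponential stand growth
   S(age) = p·S_max·(1 − e^(−r·age)) with strictly diminishing increments,
   planting programs, and ±20% perturbation support for sensitivity work.
5. **GHG inventory** — enteric and manure CH₄, direct/indirect N₂O, energy
   and embedded CO₂, converted at GWP₁₀₀ of 28 (CH₄) and 265 (N₂O);
   net = gross − soil accrual − tree removals; net-zero is defined on the
   20-year mean of annual net emissions after a 6-year spin-up discard;
   emissions intensity uses protein-mass allocation between meat and wool.
6. **Interventions** — a composable algebra over a catalog of adaptation
   bundles (Low Hanging Fruit, Towards Carbon Neutral, Income
   Diversification, Carbon Neutral packages CN1–CN4) including an
   *Asparagopsis taxiformis* feed additive (80% enteric CH₄ inhibition), a
   methane vaccine (30%), incremental and transformational feed-conversion
   efficiency (+10/15% and +20/30%), biochar, lucerne renovation and tree
   plantings (beef 50–110 ha plantation; sheep 200–220 ha environmental).
7. **Economics** — EBIT with a Gaussian-copula correlated-price Monte Carlo
   (10,000 iterations by default), a hybrid carbon policy ($80/Mg CO₂e tax
   on residual net emissions, $28/Mg CO₂e credit when net-negative), and
   marginal abatement cost curves ($ per Mg CO₂e mitigated).
8. **Impact assessment** — a normalised multidimensional score: production,
   profit and (inverse-coded) net emissions each normalised by the set
   maximum and summed on a 0–3 scale, plus ternary-plot coordinates and a
   sensitivity-sweep engine (CH₄ inhibition 10–99% × tree growth ±20%).

## Worked example

```python
from grazecast import pipeline as pl

cfg = pl.RunConfig(farm="beef", horizon="2030", seed=1)
base = pl.run_scenario(cfg, "BASE")
asp = pl.run_scenario(cfg, "ASP")
for r in (base, asp):
    print(f"{r.label}: net {r.net.mean_net:,.0f} Mg CO2e/yr, "
          f"pre-tax profit ${r.profit.mean:,.0f}, "
          f"post-account ${r.account.post_account_profit:,.0f}")
```

```
BASE: net 2,082 Mg CO2e/yr, pre-tax profit $443,254, post-account $276,700
ASP: net 531 Mg CO2e/yr, pre-tax profit $373,254, post-account $330,783
```

The unmitigated beef fixture emits ~2,100 Mg CO₂e/yr on net and loses
~$167k/yr to the carbon tax. Feeding the methane-inhibiting seaweed
supplement costs $70k/yr in its own right (pre-tax profit falls), but cuts
net emissions by ~75%, and the avoided tax leaves the business ~$54k/yr
better off after carbon accounting — the hybrid policy's intended
incentive.

The same flow from a shell:

```bash
grazecast run --farm beef --horizon 2030 --bundle ASP --seed 1 --out out/
grazecast compare --farm beef --horizon 2030 --seed 1 --bundles ASP,CN1
grazecast macc --farm beef --horizon 2030 --seed 1 --bundles ASP,LHF,CN1
grazecast sweep --farm beef --horizon 2030 --seed 1 \
    --inhibition 0.1:0.99:5 --trees -0.2:0.2:3 --area 80
```

`compare` prints the per-scenario impact scores (for example
`CN1: production 1.00 + profit 0.80 + emissions 1.00 = 2.80 / 3`), `macc`
the abatement cost curve (a negative cost means the intervention pays for
itself), and `sweep` writes the sensitivity grid as CSV.

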