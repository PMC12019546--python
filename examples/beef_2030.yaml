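# Beef fixture, 2030 horizon, default hybrid carbon policy.
farm: beef
horizon: "2030"
seed: 1
mc_iterations: 10000
policy:
  tax_rate: 80.0
  credit_price: 28.0
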