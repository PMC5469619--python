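species:
- id: S1
  r0: -0.05
- id: S2
  r0: -0.05
mediators:
- id: C1
  kind: consumable
  C0: 500.0
  supply: 50.0
- id: C2
  kind: consumable
  C0: 2000.0
  supply: 0.0
links:
- mediator: C1
  beta: 0.0
  consumer: S1
  alpha: 1.0e-06
  consumption: yield
  target: S1
  r_effect: 0.4
  K_effect: 5.0
  effect_form: saturable
  co_limitation: false
- mediator: C1
  beta: 0.0
  consumer: S2
  alpha: 1.0e-06
  consumption: yield
  target: S2
  r_effect: 0.4
  K_effect: 1.0
  effect_form: saturable
  co_limitation: true
- mediator: C2
  producer: S1
  beta: 2.5e-07
  consumer: S2
  alpha: 1.0e-05
  consumption: yield
  target: S2
  r_effect: 0.4
  K_effect: 10000.0
  effect_form: saturable
  co_limitation: true
initial_densities:
  S1: 10000.0
  S2: 10000.0
dilution:
  mode: none
  threshold: 0.0
  reset_total: 0.0
  dilute_mediators: true
S_ext: 0.01
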