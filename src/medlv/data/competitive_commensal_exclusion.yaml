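species:
- id: S1
  r0: -0.03775730042575439
- id: S2
  r0: -0.07858659823529499
mediators:
- id: C1
  kind: consumable
  C0: 352.5475027426453
  supply: 35.25475027426453
- id: C2
  kind: consumable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  beta: 0.0
  consumer: S1
  alpha: 1.0075899992712997e-06
  consumption: yield
  target: S1
  r_effect: 0.6351210207241113
  K_effect: 17.1783136327516
  effect_form: saturable
  co_limitation: false
- mediator: C1
  beta: 0.0
  consumer: S2
  alpha: 5.000104447181724e-07
  consumption: yield
  target: S2
  r_effect: 0.3838937983576764
  K_effect: 29.1807562837069
  effect_form: saturable
  co_limitation: true
- mediator: C2
  producer: S1
  beta: 1.631998222662204e-07
  consumer: S2
  alpha: 9.663786054496463e-08
  consumption: yield
  target: S2
  r_effect: 0.3838937983576764
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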