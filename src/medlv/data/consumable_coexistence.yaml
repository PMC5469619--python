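species:
- id: S1
  r0: 0.5
- id: S2
  r0: 0.3
mediators:
- id: C1
  kind: consumable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  producer: S1
  beta: 0.0003
  consumer: S2
  alpha: 0.0006
  K_consume: 2000.0
  consumption: kinetic
  target: S2
  r_effect: 0.5
  K_effect: 2000.0
  effect_form: saturable
  co_limitation: false
initial_densities:
  S1: 50000000.0
  S2: 50000000.0
dilution:
  mode: turbidostat
  threshold: 1000000000.0
  reset_total: 100000000.0
  dilute_mediators: true
S_ext: 0.01
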