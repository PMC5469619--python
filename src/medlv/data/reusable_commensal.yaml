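species:
- id: S1
  r0: 0.3
- id: S2
  r0: 0.1
mediators:
- id: C1
  kind: reusable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  producer: S1
  beta: 0.0001
  alpha: 0.0
  consumption: kinetic
  target: S2
  r_effect: 0.3
  K_effect: 10000.0
  effect_form: saturable
  co_limitation: false
initial_densities:
  S1: 5000000.0
  S2: 5000000.0
dilution:
  mode: turbidostat
  threshold: 100000000.0
  reset_total: 10000000.0
  dilute_mediators: true
S_ext: 0.01
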