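species:
- id: S1
  r0: 0.49929354925440605
- id: S2
  r0: 0.34686430500393206
- id: S3
  r0: 0.49929354925440605
mediators:
- id: C1
  kind: consumable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  producer: S1
  beta: 0.0009261446445432471
  consumer: S2
  alpha: 0.0014391834857320957
  K_consume: 63.33113312241664
  consumption: kinetic
  target: S2
  r_effect: 0.677313073957109
  K_effect: 63.33113312241664
  effect_form: saturable
  co_limitation: false
- mediator: C1
  beta: 0.0
  consumer: S3
  alpha: 0.010361941433681826
  K_consume: 63.33113312241664
  consumption: kinetic
  r_effect: 0.0
  effect_form: saturable
  co_limitation: false
initial_densities:
  S1: 3333333.3333333335
  S2: 3333333.3333333335
  S3: 3333333.3333333335
dilution:
  mode: turbidostat
  threshold: 100000000.0
  reset_total: 10000000.0
  dilute_mediators: true
S_ext: 0.01
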