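species:
- id: S1
  r0: 0.16985129320739795
- id: S2
  r0: 0.21368684868292157
- id: S3
  r0: 0.17689291622958325
mediators:
- id: C1
  kind: reusable
  C0: 0.0
  supply: 0.0
- id: C2
  kind: reusable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  producer: S1
  beta: 0.00013000643623885616
  alpha: 0.0
  consumption: kinetic
  target: S2
  r_effect: 0.16676384132098132
  K_effect: 5026.373535435786
  effect_form: saturable
  co_limitation: false
- mediator: C2
  producer: S2
  beta: 3.580265278251031e-05
  alpha: 0.0
  consumption: kinetic
  target: S3
  r_effect: 0.12113266407019821
  K_effect: 472.0864714308083
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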