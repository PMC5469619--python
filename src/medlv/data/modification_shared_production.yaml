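species:
- id: S1
  r0: 0.29982419443833364
- id: S2
  r0: 0.07364544456043572
- id: S3
  r0: 0.29982419443833364
mediators:
- id: C1
  kind: reusable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  producer: S1
  beta: 9.114025528516975e-05
  alpha: 0.0
  consumption: kinetic
  target: S2
  r_effect: 0.1601069713461779
  K_effect: 20.265265884875085
  effect_form: saturable
  co_limitation: false
- mediator: C1
  producer: S3
  beta: 9.114025528516975e-05
  alpha: 0.0
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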