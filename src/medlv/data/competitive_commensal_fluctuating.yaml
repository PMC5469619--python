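species:
- id: S1
  r0: -0.08491332914738137
- id: S2
  r0: -0.0416488653908947
mediators:
- id: C1
  kind: consumable
  C0: 371.7861579668547
  supply: 37.17861579668547
- id: C2
  kind: consumable
  C0: 0.0
  supply: 0.0
links:
- mediator: C1
  beta: 0.0
  consumer: S1
  alpha: 1.4931443096943142e-06
  consumption: yield
  target: S1
  r_effect: 0.23166276028253746
  K_effect: 5.683107631469838
  effect_form: saturable
  co_limitation: false
- mediator: C1
  beta: 0.0
  consumer: S2
  alpha: 1.6545299954020506e-06
  consumption: yield
  target: S2
  r_effect: 0.22755258683947707
  K_effect: 11.26814820788689
  effect_form: saturable
  co_limitation: true
- mediator: C2
  producer: S1
  beta: 4.134050883156004e-07
  consumer: S2
  alpha: 2.395546193760262e-07
  consumption: yield
  target: S2
  r_effect: 0.22755258683947707
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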