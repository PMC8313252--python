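name: pputida_null
description: 'strain with no phytase activity: profiles unchanged'
substrate:
  InsP6: 0.95
  InsP5 [1/3-OH]: 0.05
substrate_species:
  Ins(1,2,3,4,5,6)P6: 0.95
  Ins(2,3,4,5,6)P5: 0.05
enzymes:
- name: pputida_null
  class_label: GENERIC
  w1: 1.0
  w2: 1.0
  w3: 1.0
  w4: 1.0
  w5: 1.0
  w6: 1.0
  k: 0.0
  mix: 1.0
sorption: 0.0
pi_uptake: 0.0
t_lag: 0.0
tau: 0.25
sampling_days:
- 0.0
- 2.0
baseline: 0.02
snr: 50.0
seed: 101
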