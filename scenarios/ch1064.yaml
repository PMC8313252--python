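name: ch1064
description: 'AppA-family 6-phytase isolate: 4/6-OH then two InsP4 products'
substrate:
  InsP6: 0.95
  InsP5 [1/3-OH]: 0.05
substrate_species:
  Ins(1,2,3,4,5,6)P6: 0.95
  Ins(2,3,4,5,6)P5: 0.05
enzymes:
- name: buttiauxella_appa
  class_label: HAP_6PHYTASE
  w1: 0.2
  w2: 0.001
  w3: 0.001
  w4: 0.001
  w5: 0.05
  w6: 10.0
  k: 0.2
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
seed: 104
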