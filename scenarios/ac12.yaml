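name: ac12
description: 'MINPP-like isolate: dominant 4/6-OH, smaller 5-OH, little 1/3'
substrate:
  InsP6: 0.95
  InsP5 [1/3-OH]: 0.05
substrate_species:
  Ins(1,2,3,4,5,6)P6: 0.95
  Ins(2,3,4,5,6)P5: 0.05
enzymes:
- name: ac12_minpp
  class_label: MINPP
  w1: 0.02
  w2: 0.05
  w3: 0.02
  w4: 0.8
  w5: 0.5
  w6: 1.6
  k: 0.3
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
seed: 105
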