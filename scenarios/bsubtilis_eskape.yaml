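name: bsubtilis_eskape
description: 'beta-propeller 3-phytase: partial InsP6 loss, 1/3-OH and Pi up'
substrate:
  InsP6: 0.95
  InsP5 [1/3-OH]: 0.05
substrate_species:
  Ins(1,2,3,4,5,6)P6: 0.95
  Ins(2,3,4,5,6)P5: 0.05
enzymes:
- name: bsubtilis_bpp
  class_label: BPP_3PHYTASE
  w1: 0.01
  w2: 0.01
  w3: 1.0
  w4: 0.01
  w5: 0.01
  w6: 0.01
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
seed: 102
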