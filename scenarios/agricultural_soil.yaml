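name: agricultural_soil
description: 'mixed soil community with a ~3-day lag: onset at day 3, <5% InsP6 left
  by day 5, intermediates at every level'
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
  mix: 3.0
- name: buttiauxella_appa
  class_label: HAP_6PHYTASE
  w1: 0.2
  w2: 0.001
  w3: 0.001
  w4: 0.001
  w5: 0.05
  w6: 10.0
  k: 0.2
  mix: 0.25
- name: ac12_minpp
  class_label: MINPP
  w1: 0.02
  w2: 0.05
  w3: 0.02
  w4: 0.8
  w5: 0.5
  w6: 1.6
  k: 0.3
  mix: 1.5
sorption: 0.0
pi_uptake: 0.0
t_lag: 3.2
tau: 0.25
sampling_days:
- 0.0
- 1.0
- 2.0
- 3.0
- 4.0
- 5.0
- 6.0
- 7.0
- 8.0
baseline: 0.02
snr: 50.0
seed: 106
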