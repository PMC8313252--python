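name: broadbalk_supplemented
description: 'same soil supplemented with extra phytate: 1/3-OH appears over 8 days
  while the microflora scavenge released Pi'
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
sorption: 0.4
pi_uptake: 2.0
t_lag: 3.0
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
seed: 108
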