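"""Pathway flux of position-specific enzymes down the degradation DAG.

An enzyme's positional preferences determine which intermediates a
degrading phytate molecule passes through.  The flux numbers below are
visit probabilities per chromatographic class: an AppA-type 6-phytase
funnels ~97% of molecules through InsP5 [4/6-OH], whereas a beta-propeller
3-phytase routes them through InsP5 [1/3-OH].
"""

from phytascreen import class_flux, preset_enzyme

for name in ("buttiauxella_appa", "bsubtilis_bpp", "ac12_minpp"):
    enzyme = preset_enzyme(name)
    flux = class_flux(enzyme)
    print(f"\n{name} ({enzyme.class_label}), k = {enzyme.k}/day")
    for cls in ("InsP5 [1/3-OH]", "InsP5 [2-OH]", "InsP5 [4/6-OH]", "InsP5 [5-OH]"):
        print(f"  {cls:18s} flux {flux[cls]:.3f}")
    insp4 = sorted(
        ((c, v) for c, v in flux.items() if c.endswith("P4") and v > 0.01),
        key=lambda kv: -kv[1],
    )
    print("  InsP4 intermediates above 1%:", ", ".join(f"{c} ({v:.2f})" for c, v in insp4))
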