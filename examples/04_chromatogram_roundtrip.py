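"""Forward and inverse chromatography on the clean phytate substrate.

Renders the packaged 95% InsP6 / 5% InsP5 [1/3-OH] substrate as a detector
trace, then recovers the composition by peak detection, integration and
retention-time assignment.  Noise-free, the round trip is essentially
exact: the recovered impurity reads 5.0%.
"""

from phytascreen import (
    default_retention_table,
    detect_peaks,
    integrate_and_assign,
    make_substrate,
    quantify,
    synthesize,
)

rt = default_retention_table()
substrate = make_substrate()
chrom = synthesize(substrate, rt, baseline=0.02, noise_sd=0.002, seed=42)

peaks = integrate_and_assign(detect_peaks(chrom), chrom, rt)
print("detected peaks:")
for p in peaks:
    print(f"  {p.apex_time:6.2f} min  height {p.height:6.3f}  area {p.area:6.4f}  -> {p.assigned}")

profile = quantify(peaks, normalize=True)
print("\nrecovered mole fractions of total inositol phosphate:")
for cls, frac in sorted(profile.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:18s} {100 * frac:5.2f}%")
print("\nThe ~5% InsP5 [1/3-OH] is the known contaminant of 'clean' phytate.")
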