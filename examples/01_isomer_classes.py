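"""Enumerate the chromatographically distinguishable inositol phosphate classes.

Simple anion-exchange HPLC cannot tell a myo-inositol phosphate from its
mirror image, so the 64 phosphorylation states collapse into 40 classes:
meso species elute alone, enantiomeric pairs co-elute as one peak.
"""

from phytascreen import enumerate_classes

for level in range(6, -1, -1):
    classes = enumerate_classes(level)
    names = ", ".join(c.canonical_name + (" (meso)" if c.is_meso else "") for c in classes)
    print(f"InsP{level}: {len(classes):2d} classes  {names}")

total = len(enumerate_classes())
print(f"\ntotal distinguishable classes: {total}")
print(
    "\nThe four InsP5 classes are the diagnostic ones: which OH position the\n"
    "first attack exposes (1/3, 2, 4/6 or 5) identifies the phytase family."
)
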