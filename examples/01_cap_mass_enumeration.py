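"""Enumerate the candidate cap-dinucleotide space and inspect its masses.

Builds every unordered pair of (methylated) ribonucleosides joined by a
5'-5' triphosphate under the default methylation alphabet, and prints the
[M-H]- monoisotopic masses that negative-mode LC-MS would observe.
"""

from capscape import CapStructure, Nucleoside, enumerate_caps

caps = enumerate_caps()
print(f"{len(caps)} distinct cap structures in the default alphabet\n")

for label in ("GpppG", "mGpppA", "3mGpppAm"):
    cap = next(c for c in caps if c.canonical_label == label)
    print(f"{cap.dual_label:24s} {cap.neutral_formula.composition():18s} "
          f"[M-H]- = {cap.anion_mass:.4f} Da  ({cap.cap_type})")

g = CapStructure(Nucleoside("G"), Nucleoside("G"))
mg = CapStructure(Nucleoside("G", 1), Nucleoside("G"))
print(f"\nmethyl ladder: mGpppG - GpppG = {mg.anion_mass - g.anion_mass:.7f} Da "
      "(one CH2 per methyl group)")
# Each added methyl shifts the anion mass by exactly one methylene (14.01565 Da),
# so total methyl count is read directly off the precursor mass.
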