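"""Assign observed [M-H]- masses to isobar groups of cap structures.

Takes two observed masses from the packaged detection reference and one
uncharacterised mass, matches them at 5 ppm against the enumerated
candidate space, and lists the isobar groups: structures sharing one
elemental formula cannot be told apart by precursor mass.
"""

from capscape import MassObservation, enumerate_caps, match_observation
from capscape.match import fraction_specific_structures, load_reference_detection_matrix

caps = enumerate_caps()

for mass, note in [(827.1308, "trimethylguanosine cap"), (813.1157, "four printed labels"),
                   (841.1104, "uncharacterised Y1")]:
    res = match_observation(MassObservation(mass, ">100"), caps, tolerance_ppm=5)
    print(f"observed {mass}: {res.status}")
    for g in res.isobar_groups:
        print(f"  {g.formula.composition()}  ppm={g.ppm:+.2f}  candidates: {', '.join(g.labels)}")
    if res.status == "unknown":
        near = res.nearest[0]
        print(f"  nearest (out of tolerance): {near.label} at {near.ppm:+.2f} ppm")
    print()

# Structures seen only in the shortest (20-50 nt) size fraction:
matrix = load_reference_detection_matrix()
print("specific to the 20-50 nt fraction:", fraction_specific_structures(matrix, "20-50"))
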