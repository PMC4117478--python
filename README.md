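# capscape

Tools for the computational side of RNA 5′-cap surveys on short (<200 nt)
RNAs: identifying methylated 5′-5′ cap dinucleotides from negative-mode
LC-MS masses, processing the matching small-RNA sequencing libraries, and
quantifying 2D-TLC densitometry of released cap nucleotides.

## Who this is for

An RNA 5′ cap is an inverted nucleoside — usually guanosine, methylated at
N7 and sometimes hypermethylated to N2,N2,7-trimethylguanosine (the
snRNA/snoRNA cap) — joined to the first transcribed nucleotide through a
5′-5′ triphosphate bridge. Enzymatic digestion (RNase T2 + nuclease P1)
releases the cap core as a dinucleotide `NpppM`, observed by electrospray
MS as the deprotonated anion [M−H]⁻. Labs doing cap chemistry on small-RNA
fractions need to (a) turn a described structure into an exact monoisotopic
mass, (b) assign observed masses to candidate structures within a ppm
tolerance, knowing that positional methyl isomers and the orientation of
the dinucleotide are indistinguishable by precursor mass, and (c) tie the
MS identifications back to sequencing-library annotations and TLC spot
quantification. `capscape` implements all three as a typed, tested Python
library with a thin CLI.

## The core calculation

For a nucleoside with base `N ∈ {A, C, G, U}`, `k` base N-methyls and an
optional 2′-O-methyl, the elemental formula is

    formula(N, k, ribose) = formula(ribonucleoside N) + (k + ribose)·CH2

and a cap dinucleotide's neutral formula is

    formula(outer) + formula(inner) + H5P3O10 − 2·H2O

with the [M−H]⁻ mass `M = monoisotopic(neutral) − 1.00727646`. Every
methyl shifts the mass by exactly one methylene (14.01565 Da), so the total
methyl count is read directly off the precursor mass, while its placement
is not — candidates are therefore reported in *isobar groups* sharing one
elemental formula, and mass error is the usual
`ppm = (observed − calculated)/calculated × 10⁶`.

Around this core the package provides: 3′-adapter clipping with
insert-length inference (with 100-nt reads and a minimum 8-base adapter
match, lengths 0–92 nt are measurable and 93 nt is the first that is not),
exact-match rRNA dusting, a toy exact-substring aligner for desk-scale
work, hierarchical biotype annotation (priority: unknown < intron < exon <
miRNA < snRNA < snoRNA < tRNA), size-class composition tables, TSS/TTS
window profiles, CPM-based tag-cluster enrichment, TLC plate
normalisation, and a seeded synthetic-data generator that produces every
input with per-record ground truth.

## Worked example

```python
from capscape import MassObservation, enumerate_caps, match_observation

caps = enumerate_caps()                      # 136 structures, default alphabet
res = match_observation(MassObservation(813.1157, ">100"), caps, tolerance_ppm=5)
for g in res.isobar_groups:
    print(g.formula.composition(), f"ppm={g.ppm:+.2f}", g.labels)
```

prints

```
C23H33N10O17P3 ppm=-1.01 ('2mGmpppA', '2mGpppAm', '2mGpppmA', '3mGpppA',
 'GmpppmAm', 'mGmpppAm', 'mGmpppmA', 'mGpppmAm')
```

i.e. the observed anion at 813.1157 Da matches, within 5 ppm, a single
isobar group of {G, A} caps carrying three methyl groups — including
2mGpppAm, mGpppmAm and 3mGpppA, which cannot be distinguished from one
another by precursor mass alone. An observation with no candidate in
tolerance is reported `unknown` together with its nearest out-of-tolerance
candidates, so uncharacterised masses never silently disappear.

The `examples/` directory holds one short script per capability
(enumeration and masses, mass matching, adapter clipping, library
annotation, TLC quantification); each prints the numbers it computes with
a note on what they mean. The same stages are available from the shell:

```
capscape simulate --seed 1 --outdir sim/
capscape clip --fastq sim/sRNA.fastq --out tags.fasta
capscape dust --tags tags.fasta --reference sim/rrna.fasta --out kept.fasta
capscape align-toy --tags kept.fasta --genome sim/genome.fasta --out aln.bed
capscape annotate --bed aln.bed --features sim/features.bed --out composition.csv
capscape match --obs sim/mass_observations.csv --tolerance-ppm 5 --out matches.csv
capscape tlc --spots sim/tlc_spots.csv --out tlc_summary.csv
capscape run --config run.yaml --outdir out/   # full pipeline + manifest
```

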