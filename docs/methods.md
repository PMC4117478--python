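# Methods

## Cap-dinucleotide mass model

A cap structure is modelled as an unordered pair of ribonucleosides joined
by a 5′-5′ triphosphate bridge. Formulas are integer element counts over
C/H/N/O/P; each base N-methyl or 2′-O-ribose methyl adds one CH2. The
neutral dinucleotide formula is `outer + inner + H5P3O10 − 2·H2O` (two
waters leave when the bridge's phosphoester bonds form) and the observed
species is the deprotonated anion, `[M−H]⁻ = neutral − 1.00727646 Da`.
Conventions chosen where the literature leaves room:

* **Atomic masses** are frozen monoisotopic constants (C 12 exactly,
  H 1.0078250319, N 14.0030740, O 15.9949146, P 30.97376151) so golden
  test values are bit-stable.
* **Proton subtraction** for [M−H]⁻ follows the standard negative-ESI
  convention; the electron is handled implicitly. Published calculated
  masses for the same structures sit ≈2.5 mDa (≈3 ppm) *below* these
  values for every assigned structure we checked; the source's mass
  convention is not stated, so agreement is asserted at ≤5 ppm rather than
  to the printed digit.
* **7-methylguanosine** caps are treated as formula-neutral zwitterions:
  methylation changes composition by CH2 only, no charge correction.
* **Methyl placement is not tracked** (only counts): precursor mass cannot
  distinguish N2,N2- from N2,7-dimethylguanosine, so candidates are
  reported in isobar groups and labels are compared after stripping
  retention-time isomer suffixes like `(1)`/`(2)`.

The default enumeration alphabet allows 0–3 base methyls on G (covering
7mG, 2,7mG and the 2,2,7mG trimethylguanosine cap), 0–1 on A (N6), none on
C/U, plus one optional 2′-O-methyl on every nucleoside — 16 nucleoside
variants, 136 unordered caps. This covers every assigned structure in the
packaged detection reference without inflating the search space; the
alphabet is configurable (YAML) for extended searches. The default match
tolerance is 5 ppm: the largest published error among assigned rows is
3.00 ppm, and 5 ppm also absorbs the calculated-mass offset above.
Matching is classification-complete by construction: distinct formulas in
the default alphabet are separated by ≥0.98 Da (a C↔U swap), vastly more
than any plausible tolerance, so an isobar group is recovered or the
observation is reported `unknown` with its nearest candidates.

Cap **type 0 vs type I** classification follows the position of the
2′-O-methyl: a cap is type 0 iff its first transcribed (inner) nucleoside
lacks ribose methylation. Because MS cannot orient the dinucleotide,
classification of an enumerated candidate refers to its stored
orientation; for unordered reporting the dual label `NpppM/MpppN` is used.

**Cross-validation** of MS and TLC identifications is a set intersection
keyed by 5′-cap identity. MS dinucleotides are collapsed to the
monophosphate spot of their most-methylated guanosine side (counts 0–3 →
Gp, 7mGp, 2,2mGp, 2,2,7mGp; the count-2 name is a convention since mass
cannot place the methyls), and fraction coverage is rendered as the nt
span of the union of fractions seen by both techniques.

## Read processing

Adapter clipping is literal exact matching: the leftmost position where a
prefix of the 17-nt adapter (`CTGTAGGCACCATCAAT`) matches the read exactly
— the full adapter internally, or ≥ `min_match` (default 8) bases running
to the read end — ends the insert. Mismatch-tolerant clipping is out of
scope. Consequence, asserted by property test: for read length R and
minimum match m the inferable insert lengths are exactly 0..R−m (0–92 for
R=100, m=8). Reads without a match keep their full sequence and are
flagged length-unmeasured.

rRNA dusting removes a tag iff its clipped sequence is an exact substring
of the rDNA reference *or its reverse complement* — the conservative,
strand-agnostic reading, since reference dusting tools vary. Empty inserts
are kept (no sequence evidence). The toy aligner is an exact-substring
scan of both strands reporting all hits, with `unique` true for single
hits; it stands in for a real aligner at desk scale only and is validated
against a naive quadratic scan. Coordinates are 0-based half-open (BED
native) throughout; SAM input is converted on ingestion via pysam.

## Annotation and enrichment

Biotype resolution takes the maximum-priority biotype among features
overlapping the alignment by ≥1 nt, priorities (ascending): unknown,
intron, exon, miRNA, snRNA, snoRNA, tRNA. Overlap is strand-aware by
default with an `ignore_strand` escape hatch; multi-mapping tags are
excluded from composition counts by default. Length bins are 0–18, 19–29,
30–50, 51–100, 101–200 nt: the two upper classes are published as
“51–100” and “100–200”, which overlap at 100; we resolve 100 into 51–100
so the bins partition, and unmeasured and >200 lengths get their own
classes.

TSS/TTS profiling counts tag 5′ ends inside half-open 100-nt windows
centred on site positions. Cluster enrichment merges overlapping tag
intervals across all libraries (single linkage, strand-blind), normalises
per-library counts to CPM, and scores
`log2((mean treatment CPM + p)/(mean control CPM + p))` with pseudocount
p = 1 CPM; this simple fold change (not a count-model test) is a declared
stand-in — the analyses it emulates report fold changes only. Note that at
desk-scale library depths a single tag is ~10³ CPM, so singleton
treatment-only clusters dominate raw fold-change rankings; enrichment
conclusions should be drawn among expressed clusters (the tests use a
minimum mean-expression filter of ~3 tags/library for exactly this
reason), mirroring how such plots weight clusters by average expression.

## TLC quantification

Per plate: percentages are `100·max(raw−background, 0) / Σ max(raw−background, 0)`
over non-saturated spots; origins are saturated in practice and therefore
marked and excluded from numerator and denominator alike. Negative
background-subtracted intensities clamp to zero with a warning. Replicate
summaries report the arithmetic mean, sample SD (n−1; zero for a single
replicate) and n per (fraction, spot); spots missing from a replicate are
treated as absent, not zero. Percentages are invariant under a common
scaling of intensities and background, so plates of different exposure are
directly comparable.

## Synthetic-data generator

The generator emulates the targeted experimental design, with all
randomness derived from one seed (per-stage independent streams; identical
seeds give byte-identical files):

* **Genome**: 100 kb random sequence, 20 non-overlapping features per
  biotype (intron, exon, miRNA, snRNA, snoRNA, tRNA) with class-typical
  footprints, plus a designated 2-kb tail segment that serves as the
  synthetic rDNA unit — so rRNA dusting needs no external reference. Every
  feature sequence is verified unique in the genome (either strand).
* **Libraries**: 100-nt reads = insert + 17-nt 3′ adapter + random fill.
  Inserts are drawn 5′-anchored from planted features under per-library
  biotype mixtures with truncated-normal lengths (published sources give
  ranges, not distributions). The plain sRNA library is miRNA-dominated
  with a 22±1.5 nt insert mode (modal clipped length 20–24 nt); the capped
  library plants processed snoRNA/tRNA fragments below 50 nt; the CAGE
  library cleaves inserts to a fixed 27 nt before adapter ligation
  (EcoP15I-style); the IP library is 50% snRNA versus 5% in its
  no-antibody control. rRNA contaminants are injected at 5%.
* **Mass observations**: observed = true [M−H]⁻ × (1+ε), ε ~ N(0, 1.5 ppm),
  200 observations by default, with the generating structure and formula
  recorded per observation.
* **TLC plates**: raw = truth% × plate scale + background + Gaussian noise
  (sd 1% of scale), three replicates, plus a saturated origin spot per
  plate.

What the generator does **not** model: sequencing errors and quality
scores, PCR duplication, expression heterogeneity within a biotype,
genome repeat structure, adapter mismatches, retention times, and isotope
patterns. Passing end-to-end tests therefore demonstrates correctness of
the pipeline's logic under clean, known-truth conditions, not performance
on real libraries — e.g. real-data annotation percentages are not
reproducible here and are not asserted anywhere.

## Problem sizes and numerics

Tests run the full stack at desk scale — 2,000 reads per simulated
library, 100-kb genome, 200 mass observations, the annotation oracle at
1,000 tags × 10,000 features — chosen so the whole suite completes in
seconds while keeping multinomial sampling error well inside the asserted
4σ binomial bands. Composition fractions sum to 1 within 1e-9; plate
percentages to 100 within 1e-9; mass algebra is exact integer bookkeeping
with floating summation only at the final dot product (verified against an
independent mass library to 5e-5 Da and an independent per-atom summation
to 1e-9 Da). Deterministic candidate ordering (by mass, then label) and
fixed CSV formatting (6-decimal masses, 2-decimal ppm) keep outputs
byte-reproducible for golden-file comparison.

## Known limitations

* Precursor-mass matching only; MS/MS fragment interpretation is out of
  scope, so positional isomers stay grouped.
* The Yn (uncharacterised) masses are reported with nearest candidates,
  never force-assigned; extending the alphabet (e.g. methylated C/U) is
  possible via configuration but not default.
* The toy aligner is exact-match and quadratic-ish; real data should be
  aligned externally and ingested as SAM/BED.
* Cluster enrichment has no significance testing and no dispersion model.
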