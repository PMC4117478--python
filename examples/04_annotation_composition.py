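"""Simulate a capped small-RNA library and recover its biotype composition.

Generates a synthetic genome with planted features, sequences a capped
small-RNA library, clips adapters, removes rRNA contaminants, aligns the
tags and resolves each one to the highest-priority overlapping biotype,
then tabulates composition per length bin.
"""

from capscape import (
    SimulationConfig,
    annotate_tags,
    clip_adapter,
    composition_table,
    gen_genome_and_annotation,
    gen_library,
    rrna_filter,
    toy_align,
)

config = SimulationConfig(seed=1, reads_per_library=1500)
sim = gen_genome_and_annotation(config)
reads, truth = gen_library(config, "capped_sRNA", sim)

tags = [clip_adapter(r.sequence, config.adapter, 8, r.read_id, "capped", "capped_sRNA")
        for r in reads]
kept, removed = rrna_filter(tags, sim.rrna)
alignments = toy_align(kept, sim.genome)
print(f"{len(reads)} reads -> {len(kept)} kept after rRNA dusting "
      f"({len(removed)} removed) -> {len(alignments)} aligned")

table = composition_table(annotate_tags(alignments, sim.features),
                          group_by=("length_bin",))
bin3050 = table[table.length_bin == "30-50"].sort_values("fraction", ascending=False)
print("\ncomposition of the 30-50 nt bin (fractions sum to 1):")
print(bin3050.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
# The 30-50 nt bin is dominated by tRNA/snoRNA fragments: the library's
# mixture plants processed fragments of these biotypes below 50 nt.
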