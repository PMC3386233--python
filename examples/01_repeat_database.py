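"""Build an annotated repeat-locus database from a masking hit table.

Generates a synthetic genome with implanted HERV-like copies, emits the
per-part masking hits, and assembles them into structured elements.
"""

import io

from hervarray import DbConfig, assemble_elements, elements_to_table, parse_repeat_hits
from hervarray.simulate import SimConfig, make_genome_and_repeats, truth_to_repeat_hits

config = SimConfig(seed=11, genome_length=80_000, copies_per_family={"HVW": 5})
genome, truth = make_genome_and_repeats(config)

hit_table = truth_to_repeat_hits(truth)
hits, report = parse_repeat_hits(
    io.StringIO(hit_table.to_csv(sep="\t", index=False)), DbConfig()
)
elements = assemble_elements(hits, DbConfig())

print(f"{report.n_kept} hits retained (max divergence 20%), "
      f"{report.n_dropped_divergence} dropped")
print(elements_to_table(elements)[["locus_id", "start", "end", "strand", "structure"]])
print()
print("Each row is one assembled locus; solo_LTR means only U3/R/U5 parts are")
print("present, with no internal gag/pol/env sequence between two LTR blocks.")
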