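"""Characterize the +/-50 kb gene and GC environment of LTRs.

Places a gene annotation with a sense-free 8 kb zone upstream of every
implanted locus (the geometry observed around promoter LTRs) and shows the
gene-density ratio, placements and the upstream-sense cumulative curve.
"""

import io

from hervarray import DbConfig, assemble_elements, parse_repeat_hits
from hervarray.genomic_env import (
    build_context,
    cumulative_gene_occurrence,
    gene_density_ratio,
)
from hervarray.simulate import (
    SimConfig,
    make_gene_annotations,
    make_genome_and_repeats,
    truth_to_repeat_hits,
)

config = SimConfig(seed=51, genome_length=400_000, copies_per_family={"HVW": 10},
                   gene_density=8.0, promoter_zone_rule=True)
genome, truth = make_genome_and_repeats(config)
genes = make_gene_annotations(config, truth)
hits, _ = parse_repeat_hits(
    io.StringIO(truth_to_repeat_hits(truth).to_csv(sep="\t", index=False)), DbConfig()
)
elements = assemble_elements(hits, DbConfig())

contexts = [build_context(e, genes, genome=genome) for e in elements]
print(f"{len(genes)} genes, {len(contexts)} LTR loci")
print(f"gene density ratio (neighbors per LTR in +/-50 kb): "
      f"{gene_density_ratio(contexts):.2f}")
for ctx in contexts[:5]:
    print(f"  {ctx.locus_id}: {len(ctx.neighbors)} neighbors, "
          f"GC {ctx.gc_fraction:.3f}, {ctx.placement}")

intergenic = [c for c in contexts if c.is_intergenic]
curve_sense = cumulative_gene_occurrence(intergenic, "upstream", "sense", step=2_000)
curve_anti = cumulative_gene_occurrence(intergenic, "upstream", "antisense", step=2_000)
print(f"\nupstream cumulative gene occurrence over {len(intergenic)} intergenic LTRs:")
print("  distance   sense  antisense")
for (_, s), (_, a) in zip(curve_sense.iterrows(), curve_anti.iterrows()):
    if s["distance"] % 4000 == 0:
        print(f"  {int(s['distance']):>8}   {int(s['count']):>5}  {int(a['count']):>9}")
print("The sense column stays at 0 below 8 kb -- the generator enforces the")
print("sense-free upstream zone that distinguishes promoter-like loci.")
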