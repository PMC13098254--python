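"""Cluster proteomes into gene families and trace the core-genome curve.

Greedy longest-first identity clustering (CD-HIT style, 90% threshold)
builds gene families; strains are ordered by shared gene count and the core
genome is the running intersection along that ordering.
"""
from pangem import (
    ProteinRecord,
    WorldConfig,
    build_presence_matrix,
    cluster_gene_families,
    cluster_strain_blocks,
    core_genome_curve,
    generate_world,
    order_strains_by_shared,
)

world = generate_world(WorldConfig(seed=1))
records = [ProteinRecord(s, g, seq) for s, genes in world.proteomes.items() for g, seq in genes]
families = cluster_gene_families(records, 0.9)
matrix = build_presence_matrix(families, world.strains)
curve = core_genome_curve(matrix, order_strains_by_shared(matrix))

print(f"gene families: {len(families)} (truth: {len(world.families)})")
print(f"pan-genome size: {matrix.pan_size()}, core size: {matrix.core_size()}")
print(f"core curve: starts at {curve.sizes[0]}, ends at {curve.sizes[-1]}")
blocks = cluster_strain_blocks(matrix, 3)
print(f"strain blocks (Jaccard/average-linkage, k=3): {sorted(set(blocks.values()))}")
# The curve's first value is the most gene-rich strain's family count; the
# final value is the 30 core families every strain carries.
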