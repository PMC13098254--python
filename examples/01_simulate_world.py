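"""Generate a synthetic multi-strain world and inspect its ground truth.

Builds the default 24-strain panel: core/accessory/rare gene families with
allele variation, a toy universal metabolic network whose gene-gated
pathways fix each strain's true substrate phenotypes, and simulated
phenotype-microarray plates.
"""
from pangem import WorldConfig, generate_world

world = generate_world(WorldConfig(seed=1))

print(f"strains: {len(world.strains)}, gene families: {len(world.families)}")
print(f"substrates: {world.substrates}")
print("genes per strain (first 5):")
for strain in world.strains[:5]:
    print(f"  {strain}: {len(world.proteomes[strain])} genes")
print("\ntrue growers per substrate:")
print(world.true_phenotype.sum().to_string())
# Each count is the number of strains whose gene content completes that
# substrate's catabolic pathway; sub01 is gated by core families, so all
# strains grow on it, the rest depend on accessory-family presence.
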