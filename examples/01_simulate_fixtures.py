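"""Simulate a multi-pool maize panel and write plain-text fixtures.

Builds a two-chromosome toy genome with telomere-enriched polymorphism,
a small Dent/Flint panel with trios and a replicate, caller-style
sequencing records and two-channel intensities, then writes VCF / TSV /
BED fixtures plus a manifest.
"""

from pathlib import Path

from maizearray import simulate

genome = simulate.simulate_genome(simulate.GenomeConfig(), seed=1)
panel = simulate.default_panel()
truth = simulate.simulate_panel(genome, panel, n_variants=500, seed=1)
calls = simulate.simulate_sequencing_calls(truth, paralog_fraction=0.1, seed=1)
intensities = simulate.simulate_intensities(truth, seed=1)

out = Path("scratch/fixtures")
manifest = simulate.write_fixture_set(
    out, genome=genome, panel=panel, calls=calls, intensities=intensities,
    seed=1, settings={"n_variants": 500},
)

print(f"genome: {len(genome.chromosomes)} chromosomes, "
      f"{genome.total_length:,} bp, {len(genome.genes)} genes")
print(f"panel: {truth.n_samples} samples, {truth.n_variants} variants")
print("planted categories:",
      truth.variants["planted_category"].value_counts().to_dict())
print(f"fixtures written to {out}: {sorted(manifest['files'].values())}")
# The planted category counts show the mixture of cluster geometries the
# genotype caller will later have to recover; everything on disk is plain
# text and round-trips through maizearray.vcfio.
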