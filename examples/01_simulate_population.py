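"""Simulate a diploid F2 resequencing population with known crossover truth.

Builds a 2-chromosome toy genome with pericentromeric suppression, phased
parental SNPs and a gene/TE annotation, then samples 60 selfed F2
individuals at ~14x depth and writes the study to VCF/GFF3/BED/TSV.
"""

import tempfile

from xomap import RateLandscape, SimConfig, simulate_f2, simulate_genome
from xomap.io import write_outputs

config = SimConfig(n_individuals=60, chrom_lengths=(6_000_000, 5_000_000), seed=11)
genome, annotation, variants = simulate_genome(config)
landscape = RateLandscape.for_genome(genome, pericentromere_factor=0.02)
matrix, truth = simulate_f2(genome, variants, landscape, config)

print(f"genome: {len(genome.names)} chromosomes, {genome.total_length() / 1e6:.0f} Mb total")
print(f"phased SNPs: {variants.n_snps()} ({len(annotation.genes)} genes annotated)")
counts = truth.counts_per_individual()
print(f"true crossovers per F2 individual: mean {counts.mean():.2f}, range {counts.min()}-{counts.max()}")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_outputs(tmp, genome, annotation, variants, matrix=matrix, truth=truth)
    print("files written:", ", ".join(sorted(paths)))

# The mean reflects ~1.25 crossovers per chromosome per individual (two
# meioses with an obligate bivalent crossover transmitted to each gamete
# with probability 1/2); the truth TSV carries every simulated event.
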