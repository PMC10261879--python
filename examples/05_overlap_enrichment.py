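"""Genomic-feature overlap of high-resolution crossovers, with a Monte
Carlo enrichment test.

Filters detected intervals to the high-resolution (<5 kb) dataset, derives
feature classes from the annotation, and compares observed overlap rates
with 10,000 random re-placements of the same interval lengths.
"""

from xomap import (
    RateLandscape,
    SimConfig,
    derive_features,
    detect_crossovers,
    filter_high_resolution,
    monte_carlo_null,
    simulate_f2,
    simulate_genome,
    summarize_sizes,
)

config = SimConfig(n_individuals=150, chrom_lengths=(8_000_000,) * 3, seed=51)
genome, annotation, variants = simulate_genome(config)
landscape = RateLandscape.for_genome(genome, pericentromere_factor=0.02)
matrix, _ = simulate_f2(genome, variants, landscape, config)
result = detect_crossovers(matrix, genome, mode="refined")

hires = filter_high_resolution(result.intervals, max_width=5000)
sizes = summarize_sizes(result.intervals)
print(
    f"refined intervals: {sizes.n} (median {sizes.median_bp:.0f} bp, "
    f"{100 * sizes.frac_lt_5kb:.1f}% below 5 kb); high-resolution dataset: {len(hires)}"
)

features = derive_features(annotation, genome)
mc = monte_carlo_null(
    hires, features, genome, m=10_000, seed=52, classes=["gene", "intergenic", "tss_u1k", "intron"]
)
cols = ["feature", "observed_pct", "null_mean_pct", "null_sd_pct", "p", "direction"]
print(mc.table[cols].round(3).to_string(index=False))

# Crossovers concentrate in euchromatin where the genes are, so the genic
# observed rate exceeds the genome-random null (enriched) while the
# intergenic rate falls below it (depleted); P is the add-one two-sided
# empirical estimate over the 10,000 replicates.
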