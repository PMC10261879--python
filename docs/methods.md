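# Methods

This note documents the models and procedures `xomap` implements, the
defaults it ships, the numerical choices behind them, and what the bundled
simulator does and does not establish about real data.

## Population and genotype model

An F2 individual is the union of two independent meiotic products of a
heterozygous F1.  Coding SNP genotypes against the phased parental
haplotypes gives each individual a chromosome-length string over
{A, H, B}; crossovers are the transitions.  Marginally every SNP segregates
1:2:1 (A:H:B), which the bin-map χ² test takes as its null.

Read support at a SNP is modelled as total depth ~ Poisson(λ) and parent-B
read count ~ Binomial(depth, p) with p ∈ {ε, 1/2, 1−ε} for genotypes
{AA, AB, BB}; ε (default 0.005) is the per-read base-call/mismapping error.
λ defaults to 14 (the deep regime); 1.5–3 is the shallow regime.

### Per-SNP calling (defaults)

| parameter | default | role |
|---|---|---|
| `min_depth` | 3 reads | below it: NA |
| `hom_max` | 0.1 | max minor-allele fraction for A/B |
| `het_band` | [0.25, 0.75] | parent-A fraction for H |

The gaps (0.1–0.25 and 0.75–0.9) are deliberate dead zones mapped to NA:
ratios there are as consistent with an undercalled heterozygote as with a
homozygote, and refusing the call avoids flip-flop boundaries.  Raising
`min_depth` can only convert calls to NA, never the reverse.

### Window genotyping

*Physical* windows (1 Mb, step 100 kb — the coarse grid) pool allele depths
over their SNPs and apply the same ratio logic (A ≥ 0.9, B ≤ 0.1,
H ∈ [0.25, 0.75], ≥ 10 pooled reads).  Pooling is what makes 1.5–3×
populations genotypeable: a 1 Mb window at 1 SNP/kb and 2× depth pools
~2,000 reads.  *SNP-count* windows (15 SNPs, step 1 — the fine grid) take a
majority vote over non-missing per-SNP calls, requiring ≥ 8 informative
SNPs and ≥ 80% agreement; voting is the right tool at 14× where individual
calls are mostly correct.  Truncated terminal windows are kept when they
meet the informativeness threshold.

## Crossover detection

**Coarse stage.**  Non-NA window calls are collapsed into segments with NA
windows transparent (low-coverage data would otherwise fragment segments).
Each adjacent segment pair with different genotypes yields a candidate
breakpoint at the mean of the left anchor bin's end and the right anchor
bin's start — with the overlapping coarse grid this is the centre of the
two anchor windows' intersection.  Candidates whose anchor bins share a
window (a one-window middle segment) are collapsed: dropped as a blip when
the outer genotypes match, merged into a direct outer-to-outer candidate
when they differ.

**Refinement.**  The SNPs spanning the two anchor bins are re-genotyped
with the fine grid as a gate (the window-level genotype must actually
change), then the interval is tightened on per-SNP calls:

* the **right endpoint** is the first SNP of the first run of `anchor_w`
  (default 3) consecutive calls matching the new genotype;
* the **left endpoint** is the last old-genotype call before that anchor,
  preferring calls with an adjacent concordant neighbour so isolated
  discordant calls are ignored.

A homozygous call may serve as an endpoint only when its depth makes an
undercalled heterozygote implausible: total ≥ 12 reads with zero
opposite-allele reads (heterozygote probability ≤ 2⁻¹²).  This matters at
14×: a heterozygous SNP drawing Poisson depth 5 has probability 1/16 of
showing all five reads from one allele, and such a call adjacent to the
true boundary is locally indistinguishable from a genuine extension of the
homozygous run.  Disqualified endpoints step outward to the nearest
qualified call, which can only widen the reported interval, never move it
off the true position.  When refinement finds no transition (e.g. the
middle genotype of a sharp A↔B flip exists only as a pooled-ratio artifact),
the detector retries the merged outer-to-outer transition and otherwise
falls back to the coarse interval.

A↔B adjacency — impossible in one meiosis — is counted as two stacked
crossovers at the same locus, flagged `double`, and excluded from the
high-resolution dataset.

**Resolution limit.**  A window-based detector cannot separate two
crossovers whose genotype sliver is shorter than roughly one coarse window:
the sliver pools away into a ratio dead zone or an artifact call.  On toy
chromosomes of 6–8 Mb with ~1.25 COs per chromosome per individual this is
not rare, so unrestricted simulations lose a visible fraction of stacked
events (the acceptance script reports both detected and truth means).  On a
real ~740 Mb genome the same 1 Mb window is proportionally ~100× smaller
relative to the per-chromosome CO density, and the loss is correspondingly
rare.

## Bin map and segregation distortion

Chromosomes are partitioned at the union of all individuals' breakpoint
midpoints (a crossover interval has width; its midpoint defines the edge),
so every individual's genotype is constant within a bin by construction;
adjacent bins with identical genotype columns are merged.  Each bin's
non-missing A/H/B counts are tested against 1:2:1 with a χ² goodness-of-fit
(df = 2); bins with raw P < 0.001 are flagged, with no multiple-testing
correction — the flag is a screening annotation, not an inference.  The
population summary reports flagged-bin count, summed length (Mb) and % of
genome.

## Recombination landscape

Rates follow the two formulas

    WinRcRate   = WinCoCounts / N × 100          (cM per window)
    GenomeRcRate = Σ WinCoCounts / (WinCounts × N) × 100

with a crossover assigned to every window containing its interval midpoint
(an interior event on a size/step = 2 grid is counted twice), terminal
truncated windows included in `WinCounts`.  `GenomeRcRate` is identically
the mean of `WinRcRate` over windows.

Hotspots are maximal merged runs of windows with rate ≥ threshold; the
threshold is a free parameter reported as a fold over the genome rate.  The
deep-sequenced study scales are 12 cM/2 Mb (≈ 3.2–3.9× the population mean
rates of 3.06–3.78 cM/2 Mb) and 2.4 cM/50 kb (≈ 29× the 0.084 cM/50 kb
genome rate); on toy genomes whose pericentromere occupies only ~25% of the
chromosome the genome mean is less diluted and a 2–2.5× fold is the
comparable operating point.  Shared hotspots across populations are regions
covered by hotspot calls in ≥ k population sets.

Suppression calls are runs of ≥ `min_run` (default 3) consecutive
euchromatic windows (window centre outside the pericentromeric mask) with
rate ≤ `low_rate` and SNP density ≥ `min_snp_per_100kb` (default 10);
windows failing the SNP-density floor are reported separately as likely
false positives, since an apparent cold window without markers is
uninformative.  Suppression regions are annotated with any overlapping
(≥ 1 bp) supplied structural-variant intervals; the defaults are explicit
stand-ins for what is a visual call in practice, and all three are
parameters.

Correlations are product-moment by default (rank-based optional):
per-chromosome crossover counts vs chromosome and euchromatin length, and
window rates vs gene/repeat/TE-class/SNP densities (and GC when sequence is
supplied), computed on the same window grid.

## Feature overlap and the Monte Carlo null

The high-resolution dataset is refined intervals with width strictly < 5 kb,
`double` events excluded.  Feature classes derive from the annotation:
introns are the gene span minus exons; intergenic is the genome complement
of gene spans; TSSsU1K/TTSsD1K are exactly 1 kb strand-aware flanks clipped
at chromosome ends.  Overlap is ≥ 1 bp; an interval may count toward
several classes, and because gene ∪ intergenic tiles the genome,
count(gene) + count(intergenic) − count(both) equals the dataset size — a
property the tests exercise on random fixtures.

The null re-places, per replicate, every observed interval at an
independent uniform location: chromosome chosen with probability
proportional to its length among chromosomes the interval fits, start
uniform so it fits.  Default 10,000 replicates.  The empirical P is the
add-one estimator on the smaller tail, doubled and capped at 1 — a valid
(super-uniform) two-sided p-value under the null, bounded below by
2/(M+1).  Direction (enriched/depleted) is the sign of observed minus null
mean.  Assembly gaps are ignored (toy genomes have none); real-genome users
should mask them from the feature classes.

## The simulator: what it emulates, and what passing tests show

`simpop` generates chromosomes (default 4 × 8 Mb, all sizes configurable)
with a central pericentromeric mask (25% of the length), phased SNPs at
1/kb (0.4× density inside the pericentromere, where repeats limit SNP
calling), a gene annotation filling 25% of euchromatin (gamma-distributed
spans around 3.5 kb with exon/intron structure and UTRs), class I TEs
concentrated in the pericentromere, class II scattered, and a satellite
core.  Crossovers per meiosis per chromosome are obligate-1 +
Poisson(μ − 1) extras (μ = 1.25), placed with density proportional to a
piecewise-constant landscape (hotspot multipliers, near-zero pericentromere,
zero inside inversion masks), each transmitted to a given gamete with
probability 1/2 (two of four chromatids).  An F2 individual therefore
averages μ crossovers per chromosome — 15 per individual at 12
chromosomes, matching the observed scale — and zero-crossover chromosomes
arise naturally.  Optional hard-core interference thinning is off by
default.  Generated sequence makes the pericentromere GC-richer than the
arms, so window GC anticorrelates with recombination.

Two validation-only switches exist because exact oracles need resolvable
events: `min_separation` rejection-samples each individual's per-chromosome
CO union until all events are at least the given distance apart, and a
landscape `margin` zeroes intensity near chromosome ends (a crossover
inside the first window leaves no flanking segment to anchor).  The oracle
scenario (200 individuals, ε = 0, 14×, 2.6 Mb separation, 1.2 Mb margins)
demonstrates that the detector is *exact on resolvable input* — every
simulated event recovered, count and position.  It deliberately does not
measure behaviour under stacked crossovers, genotyping error, segregation
distortion or assembly artifacts; the unrestricted-default runs in the
acceptance script quantify the first, and the rest are outside what the
simulator emulates (no read-level artifacts, no polyploidy, no selection).

## Numerical and interface conventions

SNP positions are 1-based (VCF convention); all intervals — windows,
features, bins, crossover intervals — are 0-based half-open, and BED
exports follow suit.  Crossover truth positions are continuous (floats).
Interval arithmetic is performed on merged, sorted numpy interval sets via
binary search and prefix sums, which keeps the Monte Carlo loop at
~10⁷ placements/second.  All randomness flows through
`numpy.random.Generator` seeded from the study config; identical config and
seed give byte-identical outputs, including file exports.

## Known limitations

* Coarse-window resolution bounds detectable crossover spacing; stacked
  events closer than ~1 window merge or vanish (see above).
* The refinement's depth qualification assumes ε ≈ 0 homozygote purity; at
  higher error rates the zero-opposite-read requirement disqualifies more
  true boundaries and intervals widen accordingly.
* Bin-map distortion flags are per-bin screening statistics; correlated
  adjacent bins mean the count of flagged bins is not a count of
  independent signals.
* The Monte Carlo null is genome-wide uniform; it does not condition on
  chromosome of origin or local SNP density.
* Genetic-distance estimation, QTL scanning, motif discovery and GO
  enrichment are out of scope: the package exports the phenotype/genotype
  tables, interval FASTA and gene lists those external tools consume.
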