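"""Synthetic F2 populations with known crossover truth.

Emulates the data a diploid F2 resequencing study produces: a toy genome
with pericentromeric heterochromatin, a gene/TE annotation, phased parental
SNPs, and an F2 selfing population in which every individual is the union of
two independent meiotic products.  Crossovers are placed under a configurable
rate landscape (hotspots, pericentromeric suppression, inversion-masked
regions) and read support is sampled under a Poisson-depth / binomial-split
model with base-call errors, at the study's high-depth (~14x) or low-depth
(~1.5-3x) regimes.

The simulator's job is to make every downstream stage testable offline
against exact ground truth; it does not simulate reads, alignment artifacts,
polyploidy or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _intervals as iv
from .genotyping import PhasedVariantSet, SNPGenotypeMatrix

__all__ = [
    "ToyGenome",
    "ToyAnnotation",
    "RateLandscape",
    "CrossoverModel",
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_genome",
    "simulate_gamete",
    "simulate_f2",
    "simulate_study",
    "generate_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ToyGenome:
    """Chromosome sizes plus a per-chromosome pericentromeric interval.

    ``centromeres[chrom]`` is the pericentromeric mask (0-based half-open);
    euchromatin is its complement within the chromosome.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self):
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
            s, e = self.centromeres[name]
            if not (0 <= s <= e <= length):
                raise ValueError(f"{name}: centromere outside chromosome")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: l for n, l in self.chromosomes}

    def euchromatin(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        s, e = self.centromeres[chrom]
        return iv.complement(np.array([s]), np.array([e]), self.lengths[chrom])

    def euchromatin_length(self, chrom: str) -> int:
        return iv.total_length(*self.euchromatin(chrom))

    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class ToyAnnotation:
    """Gene models and transposable elements on a toy genome.

    Coordinates are 0-based half-open.  Gene spans are non-overlapping (a
    deliberate simplification); exons partition each gene span with introns.
    """

    genes: pd.DataFrame  # chrom, start, end, strand, gene_id
    exons: pd.DataFrame  # gene_id, chrom, start, end
    five_utr: pd.DataFrame  # gene_id, chrom, start, end
    three_utr: pd.DataFrame  # gene_id, chrom, start, end
    tes: pd.DataFrame  # chrom, start, end, te_class ("I" or "II")
    satellites: pd.DataFrame  # chrom, start, end

    def te_set(self, chrom: str, te_class: str | None = None):
        sub = self.tes[self.tes["chrom"] == chrom]
        if te_class is not None:
            sub = sub[sub["te_class"] == te_class]
        return iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())

    def repeat_set(self, chrom: str):
        sat = self.satellites[self.satellites["chrom"] == chrom]
        return iv.union(
            self.te_set(chrom), iv.merge(sat["start"].to_numpy(), sat["end"].to_numpy())
        )


@dataclass
class RateLandscape:
    """Piecewise-constant crossover intensity per chromosome (relative units).

    ``pieces[chrom] = (edges, values)`` with ``len(edges) == len(values)+1``;
    intensity is >= 0 everywhere.  Crossover *counts* come from the
    :class:`CrossoverModel`; the landscape only shapes where they fall.
    """

    pieces: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        for chrom, (edges, values) in self.pieces.items():
            if len(edges) != len(values) + 1 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{chrom}: malformed piecewise intensity")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative intensity")

    @classmethod
    def for_genome(
        cls,
        genome: ToyGenome,
        base: float = 1.0,
        pericentromere_factor: float = 0.02,
        hotspots: dict[str, list[tuple[int, int, float]]] | None = None,
        suppressed: dict[str, list[tuple[int, int]]] | None = None,
        margin: int = 0,
    ) -> "RateLandscape":
        """Uniform euchromatic intensity with pericentromeric suppression.

        ``hotspots`` maps chrom -> [(start, end, multiplier)];
        ``suppressed`` intervals (e.g. inversions) get intensity 0; ``margin``
        bp at each chromosome end get intensity 0.
        """
        pieces = {}
        for chrom, length in genome.chromosomes:
            cuts = {0, length}
            cs, ce = genome.centromeres[chrom]
            cuts |= {cs, ce}
            if margin:
                cuts |= {min(margin, length), max(length - margin, 0)}
            for s, e, _ in (hotspots or {}).get(chrom, []):
                cuts |= {s, e}
            for s, e in (suppressed or {}).get(chrom, []):
                cuts |= {s, e}
            edges = np.array(sorted(cuts), dtype=float)
            mids = (edges[:-1] + edges[1:]) / 2
            values = np.full(mids.size, base, dtype=float)
            values[(mids >= cs) & (mids < ce)] = base * pericentromere_factor
            for s, e, mult in (hotspots or {}).get(chrom, []):
                values[(mids >= s) & (mids < e)] *= mult
            for s, e in (suppressed or {}).get(chrom, []):
                values[(mids >= s) & (mids < e)] = 0.0
            if margin:
                values[mids < margin] = 0.0
                values[mids >= length - margin] = 0.0
            pieces[chrom] = (edges, values)
        return cls(pieces)

    @classmethod
    def from_feature_density(
        cls, genome: ToyGenome, features: dict[str, tuple], base: float, boost: float
    ) -> "RateLandscape":
        """Intensity ``base`` everywhere plus ``boost`` inside the features."""
        pieces = {}
        for chrom, length in genome.chromosomes:
            s, e = features.get(chrom, (np.empty(0, int), np.empty(0, int)))
            edges = np.unique(np.concatenate(([0, length], s, e))).astype(float)
            mids = (edges[:-1] + edges[1:]) / 2
            values = np.full(mids.size, base, dtype=float)
            values[iv.points_in(s, e, mids.astype(np.int64))] += boost
            pieces[chrom] = (edges, values)
        return cls(pieces)

    def integral(self, chrom: str, start: float | None = None, end: float | None = None) -> float:
        edges, values = self.pieces[chrom]
        lo = edges[0] if start is None else start
        hi = edges[-1] if end is None else end
        seg_lo = np.clip(edges[:-1], lo, hi)
        seg_hi = np.clip(edges[1:], lo, hi)
        return float(np.sum(values * np.maximum(seg_hi - seg_lo, 0)))

    def sample_positions(self, chrom: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n positions with density proportional to the intensity."""
        edges, values = self.pieces[chrom]
        seg = values * np.diff(edges)
        total = seg.sum()
        if total <= 0 or n == 0:
            return np.empty(0, dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        u = rng.uniform(0, total, size=n)
        i = np.searchsorted(cum, u, side="right") - 1
        i = np.clip(i, 0, values.size - 1)
        pos = edges[i] + (u - cum[i]) / values[i]
        return np.sort(pos)


@dataclass(frozen=True)
class CrossoverModel:
    """Crossovers per meiosis per chromosome.

    ``mu`` is the mean bivalent crossover count: an obligate CO plus
    Poisson(mu - 1) extras (or plain Poisson(mu) with ``obligate=False``).
    With ``chromatid_thinning`` each CO is transmitted to a given gamete with
    probability 1/2 (two of four chromatids), so a gamete carries mu/2 COs on
    average and zero-crossover chromosomes arise naturally.
    ``interference_bp`` applies a hard-core thinning: a CO closer than this to
    the previously retained one (within the same meiosis) is dropped.
    """

    mu: float = 1.25
    obligate: bool = True
    chromatid_thinning: bool = True
    interference_bp: float | None = None

    def __post_init__(self):
        if self.mu <= 0 or (self.obligate and self.mu < 1):
            raise ValueError("mu must be > 0 (and >= 1 when obligate)")


def simulate_gamete(
    landscape: RateLandscape,
    chrom: str,
    rng: np.random.Generator,
    model: CrossoverModel = CrossoverModel(),
) -> np.ndarray:
    """Ordered crossover positions carried by one meiotic product."""
    if landscape.integral(chrom) <= 0:
        return np.empty(0, dtype=float)
    if model.obligate:
        n = 1 + (rng.poisson(model.mu - 1.0) if model.mu > 1 else 0)
    else:
        n = rng.poisson(model.mu)
    pos = landscape.sample_positions(chrom, int(n), rng)
    if model.interference_bp and pos.size > 1:
        keep = [0]
        for i in range(1, pos.size):
            if pos[i] - pos[keep[-1]] >= model.interference_bp:
                keep.append(i)
        pos = pos[keep]
    if model.chromatid_thinning and pos.size:
        pos = pos[rng.random(pos.size) < 0.5]
    return pos


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic F2 population.

    Defaults emulate the deep-sequenced population: ~14x mean depth, 0.5%
    base-call error, 1 phased SNP per kb (reduced in the pericentromere where
    repeats limit SNP calling), and a crossover model averaging 1.25 COs per
    bivalent so an F2 individual accumulates ~1.25 COs per chromosome.
    ``min_separation`` (bp) optionally rejection-samples each individual's
    per-chromosome CO union until all events are at least that far apart --
    a validation mode that makes every simulated event resolvable by a
    window-based detector; it is off by default.
    """

    n_individuals: int = 200
    chrom_lengths: tuple[int, ...] = (8_000_000,) * 4
    centromere_frac: float = 0.25
    snp_density_per_kb: float = 1.0
    pericentromere_snp_factor: float = 0.4
    gene_fraction: float = 0.25
    mean_gene_bp: float = 3500.0
    depth_mean: float = 14.0
    error_rate: float = 0.005
    model: CrossoverModel = field(default_factory=CrossoverModel)
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.snp_density_per_kb <= 0:
            raise ValueError("snp_density_per_kb must be > 0")
        if not (0 <= self.gene_fraction < 1):
            raise ValueError("gene_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground-truth crossovers and haplotype mosaics for a simulated F2 set."""

    samples: list[str]
    crossovers: pd.DataFrame  # individual, sample, chrom, gamete, pos
    start_haps: pd.DataFrame  # individual, chrom, gamete, hap

    def positions(self, individual: int, chrom: str) -> np.ndarray:
        df = self.crossovers
        sel = (df["individual"] == individual) & (df["chrom"] == chrom)
        return np.sort(df.loc[sel, "pos"].to_numpy())

    def gamete_mosaic(self, individual: int, chrom: str, gamete: int):
        """(crossover positions, starting haplotype) for one gamete."""
        df = self.crossovers
        sel = (
            (df["individual"] == individual)
            & (df["chrom"] == chrom)
            & (df["gamete"] == gamete)
        )
        pos = np.sort(df.loc[sel, "pos"].to_numpy())
        sh = self.start_haps
        hap = int(
            sh.loc[
                (sh["individual"] == individual)
                & (sh["chrom"] == chrom)
                & (sh["gamete"] == gamete),
                "hap",
            ].iloc[0]
        )
        return pos, hap

    def genotype_at(self, individual: int, chrom: str, coords: np.ndarray) -> np.ndarray:
        """True A/H/B genotype codes (0/1/2 = number of B haplotypes)."""
        geno = np.zeros(np.asarray(coords).shape, dtype=np.int8)
        for gamete in (0, 1):
            pos, hap = self.gamete_mosaic(individual, chrom, gamete)
            geno += (hap + np.searchsorted(pos, coords, side="right")) % 2
        return geno

    def counts_per_individual(self) -> pd.Series:
        c = self.crossovers.groupby("individual").size()
        return c.reindex(range(len(self.samples)), fill_value=0)

    def counts_by_chrom(self) -> pd.DataFrame:
        tab = self.crossovers.groupby(["individual", "chrom"]).size().unstack(fill_value=0)
        return tab.reindex(range(len(self.samples)), fill_value=0)


def _sample_region_positions(
    regions: tuple[np.ndarray, np.ndarray], rate_per_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson positions (float) within a merged interval set."""
    out = []
    for s, e in zip(*regions):
        n = rng.poisson(rate_per_bp * (e - s))
        if n:
            out.append(rng.uniform(s, e, size=n))
    if not out:
        return np.empty(0, dtype=float)
    return np.sort(np.concatenate(out))


def _simulate_snps(genome, config, rng) -> PhasedVariantSet:
    positions, allele_a, allele_b = {}, {}, {}
    rate = config.snp_density_per_kb / 1000.0
    for chrom, length in genome.chromosomes:
        eu = genome.euchromatin(chrom)
        cs, ce = genome.centromeres[chrom]
        peri = (np.array([cs]), np.array([ce]))
        raw = np.concatenate(
            (
                _sample_region_positions(eu, rate, rng),
                _sample_region_positions(peri, rate * config.pericentromere_snp_factor, rng),
            )
        )
        pos = np.unique(np.floor(raw).astype(np.int64) + 1)  # 1-based
        pos = pos[(pos >= 1) & (pos <= length)]
        ref = rng.integers(0, 4, size=pos.size)
        alt = (ref + 1 + rng.integers(0, 3, size=pos.size)) % 4
        positions[chrom] = pos
        allele_a[chrom] = _BASES[ref].astype("U1")
        allele_b[chrom] = _BASES[alt].astype("U1")
    return PhasedVariantSet(genome.names, positions, allele_a, allele_b)


def _simulate_gene_models(genome, config, rng):
    genes, exons, utr5, utr3 = [], [], [], []
    if config.gene_fraction > 0:
        mean_gap = config.mean_gene_bp * (1 - config.gene_fraction) / config.gene_fraction
        gid = 0
        for chrom, _ in genome.chromosomes:
            for rs, re_ in zip(*genome.euchromatin(chrom)):
                cur = rs
                while True:
                    cur += rng.exponential(mean_gap)
                    span = int(np.clip(rng.gamma(2.0, config.mean_gene_bp / 2.0), 500, 20000))
                    start = int(cur)
                    end = start + span
                    if end >= re_:
                        break
                    gid += 1
                    gene_id = f"gene{gid:05d}"
                    strand = "+" if rng.random() < 0.5 else "-"
                    genes.append((chrom, start, end, strand, gene_id))
                    n_ex = int(min(1 + rng.poisson(2), max(span // 300, 1)))
                    parts = rng.dirichlet(np.ones(2 * n_ex - 1)) * span
                    parts = np.maximum(np.round(parts).astype(int), 30)
                    parts[-1] = span - parts[:-1].sum()
                    if parts[-1] < 30:  # degenerate split: one exon
                        parts = np.array([span])
                        n_ex = 1
                    bounds = start + np.concatenate(([0], np.cumsum(parts)))
                    for k in range(n_ex):
                        exons.append((gene_id, chrom, int(bounds[2 * k]), int(bounds[2 * k + 1])))
                    first = (chrom, start, min(start + 150, end))
                    last = (chrom, max(end - 200, start), end)
                    head, tail = (first, last) if strand == "+" else (last, first)
                    utr5.append((gene_id, *head))
                    utr3.append((gene_id, *tail))
                    cur = end
    cols_g = ["chrom", "start", "end", "strand", "gene_id"]
    cols_f = ["gene_id", "chrom", "start", "end"]
    return (
        pd.DataFrame(genes, columns=cols_g),
        pd.DataFrame(exons, columns=cols_f),
        pd.DataFrame(utr5, columns=cols_f),
        pd.DataFrame(utr3, columns=cols_f),
    )


def _simulate_tes(genome, rng):
    tes, sats = [], []
    for chrom, length in genome.chromosomes:
        cs, ce = genome.centromeres[chrom]
        peri = (np.array([cs]), np.array([ce]))
        eu = genome.euchromatin(chrom)
        # class I (retrotransposons): dense in the pericentromere, sparse outside
        for regions, cov in ((peri, 0.45), (eu, 0.05)):
            starts = _sample_region_positions(regions, cov / 3000.0, rng)
            for s in starts:
                ln = int(np.clip(rng.gamma(2.0, 1500.0), 200, 15000))
                tes.append((chrom, int(s), min(int(s) + ln, length), "I"))
        # class II (DNA transposons): scattered genome-wide
        starts = _sample_region_positions(
            (np.array([0]), np.array([length])), 0.03 / 800.0, rng
        )
        for s in starts:
            ln = int(np.clip(rng.gamma(2.0, 400.0), 100, 4000))
            tes.append((chrom, int(s), min(int(s) + ln, length), "II"))
        mid = (cs + ce) // 2
        half = max((ce - cs) // 4, 1)
        sats.append((chrom, mid - half, mid + half))
    return (
        pd.DataFrame(tes, columns=["chrom", "start", "end", "te_class"]),
        pd.DataFrame(sats, columns=["chrom", "start", "end"]),
    )


def simulate_genome(config: SimConfig) -> tuple[ToyGenome, ToyAnnotation, PhasedVariantSet]:
    """Deterministic toy genome + annotation + phased SNPs for a config."""
    rng = np.random.default_rng(config.seed)
    chroms = [(f"chr{i + 1:02d}", int(l)) for i, l in enumerate(config.chrom_lengths)]
    centromeres = {}
    for name, length in chroms:
        half = int(length * config.centromere_frac / 2)
        centromeres[name] = (length // 2 - half, length // 2 + half)
    genome = ToyGenome(chroms, centromeres)
    variants = _simulate_snps(genome, config, rng)
    genes, exons, utr5, utr3 = _simulate_gene_models(genome, config, rng)
    tes, sats = _simulate_tes(genome, rng)
    annotation = ToyAnnotation(genes, exons, utr5, utr3, tes, sats)
    return genome, annotation, variants


def _draw_individual_meioses(landscape, chrom, rng, model, min_separation, max_tries=10000):
    """Two independent meiotic products whose CO union is resolvable."""
    for _ in range(max_tries):
        g0 = simulate_gamete(landscape, chrom, rng, model)
        g1 = simulate_gamete(landscape, chrom, rng, model)
        if min_separation is None:
            return g0, g1
        both = np.sort(np.concatenate((g0, g1)))
        if both.size < 2 or np.min(np.diff(both)) >= min_separation:
            return g0, g1
    raise RuntimeError("min_separation rejection sampling did not converge")


def simulate_f2(
    genome: ToyGenome,
    variants: PhasedVariantSet,
    landscape: RateLandscape,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SNPGenotypeMatrix, SimTruth]:
    """Simulate an F2 selfing population with allele-depth read support.

    Each individual combines two independent meiotic products.  At each SNP
    the total depth is Poisson(depth_mean) and the parent-B read count is
    binomial with success probability {error, 1/2, 1-error} for genotypes
    {AA, AB, BB}.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_individuals
    samples = [f"F2_{i + 1:04d}" for i in range(n)]
    xo_rows, hap_rows = [], []
    geno = {c: np.zeros((n, variants.positions[c].size), dtype=np.int8) for c in genome.names}
    for i in range(n):
        for chrom in genome.names:
            gametes = _draw_individual_meioses(
                landscape, chrom, rng, config.model, config.min_separation
            )
            pos_1based = variants.positions[chrom]
            for g, xo in enumerate(gametes):
                hap = int(rng.integers(2))
                hap_rows.append((i, chrom, g, hap))
                for p in xo:
                    xo_rows.append((i, samples[i], chrom, g, float(p)))
                geno[chrom][i] += (hap + np.searchsorted(xo, pos_1based, side="right")).astype(
                    np.int8
                ) % 2
    depth_a, depth_b = {}, {}
    p_b = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])
    for chrom in genome.names:
        total = rng.poisson(config.depth_mean, size=geno[chrom].shape)
        db = rng.binomial(total, p_b[geno[chrom]])
        depth_a[chrom] = (total - db).astype(np.uint16)
        depth_b[chrom] = db.astype(np.uint16)
    matrix = SNPGenotypeMatrix(variants, samples, depth_a, depth_b)
    truth = SimTruth(
        samples,
        pd.DataFrame(xo_rows, columns=["individual", "sample", "chrom", "gamete", "pos"]),
        pd.DataFrame(hap_rows, columns=["individual", "chrom", "gamete", "hap"]),
    )
    return matrix, truth


@dataclass
class SimStudy:
    """Bundle of everything one simulated population comprises."""

    config: SimConfig
    genome: ToyGenome
    annotation: ToyAnnotation
    variants: PhasedVariantSet
    landscape: RateLandscape
    matrix: SNPGenotypeMatrix
    truth: SimTruth


def simulate_study(
    config: SimConfig, landscape: RateLandscape | None = None
) -> SimStudy:
    """Simulate genome + population in one call (deterministic per seed)."""
    genome, annotation, variants = simulate_genome(config)
    if landscape is None:
        landscape = RateLandscape.for_genome(genome, pericentromere_factor=0.02)
    matrix, truth = simulate_f2(genome, variants, landscape, config)
    return SimStudy(config, genome, annotation, variants, landscape, matrix, truth)


def generate_sequence(
    genome: ToyGenome,
    variants: PhasedVariantSet | None = None,
    seed: int = 0,
    gc_euchromatin: float = 0.36,
    gc_pericentromere: float = 0.42,
) -> dict[str, np.ndarray]:
    """Random genome sequence (byte arrays) with region-dependent GC.

    The pericentromere is made GC-richer than the arms so that window GC
    content anticorrelates with recombination, as heterochromatin does in the
    potato genome.  SNP positions are set to the parent-A (reference) allele.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, length in genome.chromosomes:
        cs, ce = genome.centromeres[chrom]
        gc = np.full(length, gc_euchromatin)
        gc[cs:ce] = gc_pericentromere
        u = rng.random(length)
        # order A, C, G, T with P(C)=P(G)=gc/2
        at = (1 - gc) / 2
        idx = (u >= at).astype(np.int8) + (u >= at + gc / 2) + (u >= at + gc)
        seq = _BASES[idx].copy()
        if variants is not None:
            pos0 = variants.positions[chrom] - 1
            seq[pos0] = variants.allele_a[chrom].astype("S1")
        out[chrom] = seq
    return out
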