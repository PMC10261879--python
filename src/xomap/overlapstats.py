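"""Crossover-interval statistics and genomic-feature overlap enrichment.

Builds the high-resolution crossover dataset (refined intervals < 5 kb,
double-flagged events excluded), derives feature classes from an annotation
(gene span, exon, intron, UTRs, the strand-aware 1-kb TSS-upstream and
TTS-downstream flanks, intergenic complement, TE classes), computes observed
>= 1 bp overlap rates, and tests enrichment/depletion against a Monte Carlo
null in which every observed interval is re-placed uniformly at random
(chromosome chosen proportional to its length, start uniform so the interval
fits).  Empirical P uses the add-one estimator with the smaller tail
doubled, capped at 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _intervals as iv
from .simpop import ToyAnnotation, ToyGenome

__all__ = [
    "FeatureSet",
    "OverlapSummary",
    "SizeSummary",
    "derive_features",
    "filter_high_resolution",
    "overlap_rates",
    "monte_carlo_null",
    "summarize_sizes",
    "size_fractions",
    "export_for_downstream",
]

FEATURE_CLASSES = [
    "gene",
    "exon",
    "intron",
    "five_utr",
    "three_utr",
    "tss_u1k",
    "tts_d1k",
    "intergenic",
    "classI_TE",
    "classII_TE",
    "repeat",
]


@dataclass
class FeatureSet:
    """Typed merged-interval collections over a genome."""

    chrom_lengths: dict[str, int]
    sets: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def get(self, feature: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self.sets.get(feature, {}).get(chrom, (empty, empty.copy()))

    @property
    def classes(self) -> list[str]:
        return list(self.sets)


def _flank(genes: pd.DataFrame, lengths: dict[str, int], upstream: bool, size: int = 1000):
    """Strand-aware 1-kb flanks, clipped at chromosome ends."""
    rows = {c: ([], []) for c in lengths}
    for g in genes.itertuples():
        head = (g.strand == "+") == upstream  # flank off the start coordinate?
        if head:
            s, e = g.start - size, g.start
        else:
            s, e = g.end, g.end + size
        s = max(s, 0)
        e = min(e, lengths[g.chrom])
        if e > s:
            rows[g.chrom][0].append(s)
            rows[g.chrom][1].append(e)
    return {c: iv.merge(np.array(s, dtype=np.int64), np.array(e, dtype=np.int64)) for c, (s, e) in rows.items()}


def _df_sets(df: pd.DataFrame, chroms) -> dict:
    out = {}
    for c in chroms:
        sub = df[df["chrom"] == c]
        out[c] = iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def _read_gff3(path: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, exons, utr5, utr3 = [], [], [], []
    for g in db.features_of_type("gene"):
        gid = g.id
        genes.append((g.seqid, g.start - 1, g.end, g.strand, gid))
        for ex in db.children(g, featuretype="exon"):
            exons.append((gid, ex.seqid, ex.start - 1, ex.end))
        for u in db.children(g, featuretype="five_prime_UTR"):
            utr5.append((gid, u.seqid, u.start - 1, u.end))
        for u in db.children(g, featuretype="three_prime_UTR"):
            utr3.append((gid, u.seqid, u.start - 1, u.end))
    cols_g = ["chrom", "start", "end", "strand", "gene_id"]
    cols_f = ["gene_id", "chrom", "start", "end"]
    return (
        pd.DataFrame(genes, columns=cols_g),
        pd.DataFrame(exons, columns=cols_f),
        pd.DataFrame(utr5, columns=cols_f),
        pd.DataFrame(utr3, columns=cols_f),
    )


def derive_features(source: ToyAnnotation | str, genome: ToyGenome) -> FeatureSet:
    """Feature classes from a :class:`ToyAnnotation` or a GFF3 file.

    Introns are the gene (mRNA) span minus its exons; intergenic is the
    genome complement of gene spans; the TSS/TTS flanks are exactly 1 kb,
    strand-aware, clipped at chromosome ends.
    """
    lengths = genome.lengths
    if isinstance(source, (str, os.PathLike)):
        genes, exons, utr5, utr3 = _read_gff3(source)
        tes = pd.DataFrame(columns=["chrom", "start", "end", "te_class"])
        annotation = None
    else:
        annotation = source
        genes, exons = annotation.genes, annotation.exons
        utr5, utr3 = annotation.five_utr, annotation.three_utr
        tes = annotation.tes
    chroms = genome.names
    sets: dict[str, dict] = {
        "gene": _df_sets(genes, chroms),
        "exon": _df_sets(exons, chroms),
        "five_utr": _df_sets(utr5, chroms),
        "three_utr": _df_sets(utr3, chroms),
        "tss_u1k": _flank(genes, lengths, upstream=True),
        "tts_d1k": _flank(genes, lengths, upstream=False),
    }
    sets["intron"] = {
        c: iv.intersect(sets["gene"][c], iv.complement(*sets["exon"][c], lengths[c]))
        for c in chroms
    }
    sets["intergenic"] = {c: iv.complement(*sets["gene"][c], lengths[c]) for c in chroms}
    if annotation is not None:
        sets["classI_TE"] = {c: annotation.te_set(c, "I") for c in chroms}
        sets["classII_TE"] = {c: annotation.te_set(c, "II") for c in chroms}
        sets["repeat"] = {c: annotation.repeat_set(c) for c in chroms}
    elif not tes.empty:
        sets["classI_TE"] = _df_sets(tes[tes["te_class"] == "I"], chroms)
        sets["classII_TE"] = _df_sets(tes[tes["te_class"] == "II"], chroms)
    return FeatureSet(lengths, sets, genes)


def filter_high_resolution(intervals: pd.DataFrame, max_width: int = 5000) -> pd.DataFrame:
    """Refined intervals with width strictly below ``max_width``; stacked
    double events are excluded.  Order is preserved."""
    keep = intervals["width"] < max_width
    if "double" in intervals:
        keep &= ~intervals["double"].astype(bool)
    if "mode" in intervals:
        keep &= intervals["mode"] == "refined"
    return intervals[keep].copy()


def _overlap_matrix(dataset: pd.DataFrame, features: FeatureSet, classes) -> pd.DataFrame:
    cols = {}
    chrom = dataset["chrom"].to_numpy()
    left = dataset["left"].to_numpy()
    right = dataset["right"].to_numpy()
    for cls in classes:
        hit = np.zeros(len(dataset), dtype=bool)
        for c in np.unique(chrom):
            mask = chrom == c
            hit[mask] = iv.overlaps_any(*features.get(cls, c), left[mask], right[mask])
        cols[cls] = hit
    return pd.DataFrame(cols, index=dataset.index)


def overlap_rates(
    dataset: pd.DataFrame, features: FeatureSet, classes: list[str] | None = None
) -> pd.DataFrame:
    """Observed >= 1 bp overlap counts and rates per feature class.

    An interval may count toward several classes; the combination class
    ``gene_and_intergenic`` counts intervals touching both, so that
    count(gene) + count(intergenic) - count(both) equals the dataset size
    whenever gene and intergenic tile the genome.
    """
    classes = classes or [c for c in FEATURE_CLASSES if c in features.classes]
    hits = _overlap_matrix(dataset, features, classes)
    rows = [(cls, int(hits[cls].sum())) for cls in classes]
    if "gene" in classes and "intergenic" in classes:
        rows.append(("gene_and_intergenic", int((hits["gene"] & hits["intergenic"]).sum())))
    out = pd.DataFrame(rows, columns=["feature", "count"])
    out["rate_pct"] = out["count"] / max(len(dataset), 1) * 100.0
    return out


@dataclass
class OverlapSummary:
    """Observed vs Monte Carlo null overlap rates per feature class."""

    table: pd.DataFrame  # feature, observed_count, observed_pct, null_mean_pct,
    # null_sd_pct, p, direction
    n_intervals: int
    n_replicates: int


def _random_placements(lengths, genome: ToyGenome, rng, m: int):
    """(chrom index, start) for m replicates of every interval length."""
    chrom_lens = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    n = lengths.size
    if lengths.max(initial=0) > chrom_lens.max():
        raise ValueError("interval longer than every chromosome")
    if lengths.max(initial=0) <= chrom_lens.min():
        p = chrom_lens / chrom_lens.sum()
        ci = rng.choice(chrom_lens.size, size=(m, n), p=p)
        starts = np.floor(
            rng.random((m, n)) * (chrom_lens[ci] - lengths[None, :] + 1)
        ).astype(np.int64)
        return ci, starts
    ci = np.empty((m, n), dtype=np.int64)
    starts = np.empty((m, n), dtype=np.int64)
    for k in range(n):  # rare path: some interval exceeds the smallest chromosome
        fits = chrom_lens >= lengths[k]
        p = np.where(fits, chrom_lens, 0).astype(float)
        p /= p.sum()
        ck = rng.choice(chrom_lens.size, size=m, p=p)
        ci[:, k] = ck
        starts[:, k] = np.floor(rng.random(m) * (chrom_lens[ck] - lengths[k] + 1)).astype(np.int64)
    return ci, starts


def monte_carlo_null(
    dataset: pd.DataFrame,
    features: FeatureSet,
    genome: ToyGenome,
    m: int = 10_000,
    seed: int | np.random.Generator = 0,
    classes: list[str] | None = None,
) -> OverlapSummary:
    """Monte Carlo overlap null: each replicate re-places every observed
    interval (equal length) uniformly across the genome and records the
    class overlap rates."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = classes or [c for c in FEATURE_CLASSES if c in features.classes]
    lengths = (dataset["right"] - dataset["left"]).to_numpy(dtype=np.int64)
    n = lengths.size
    ci, starts = _random_placements(lengths, genome, rng, m)
    ends = starts + lengths[None, :]
    observed = overlap_rates(dataset, features, classes).set_index("feature")
    rows = []
    for cls in classes:
        hit = np.zeros((m, n), dtype=bool)
        for idx, chrom in enumerate(genome.names):
            fs = features.get(cls, chrom)
            mask = ci == idx
            if fs[0].size == 0 or not mask.any():
                continue
            hit[mask] = iv.overlaps_any(*fs, starts[mask], ends[mask])
        null_rates = hit.mean(axis=1) * 100.0
        obs = float(observed.loc[cls, "rate_pct"])
        hi = int(np.sum(null_rates >= obs))
        lo = int(np.sum(null_rates <= obs))
        p = min(1.0, 2.0 * (1 + min(hi, lo)) / (m + 1))
        rows.append(
            (
                cls,
                int(observed.loc[cls, "count"]),
                obs,
                float(null_rates.mean()),
                float(null_rates.std(ddof=1)) if m > 1 else 0.0,
                p,
                "enriched" if obs > null_rates.mean() else "depleted",
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "observed_count",
            "observed_pct",
            "null_mean_pct",
            "null_sd_pct",
            "p",
            "direction",
        ],
    )
    return OverlapSummary(table, n, m)


def size_fractions(widths) -> dict:
    """Median width and the fractions below the 2 kb / 5 kb cutoffs."""
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        return {"n": 0, "median_bp": float("nan"), "frac_lt_2kb": float("nan"), "frac_lt_5kb": float("nan")}
    return {
        "n": int(widths.size),
        "median_bp": float(np.median(widths)),
        "frac_lt_2kb": float(np.mean(widths < 2000)),
        "frac_lt_5kb": float(np.mean(widths < 5000)),
    }


@dataclass
class SizeSummary:
    """Interval-size statistics, overall and per chromosome."""

    n: int
    median_bp: float
    frac_lt_2kb: float
    frac_lt_5kb: float
    per_chrom: pd.DataFrame  # chrom, n, mean_width_bp, mean_rate (if track given)


def summarize_sizes(intervals: pd.DataFrame, track=None) -> SizeSummary:
    """Size statistics of refined crossover intervals."""
    refined = intervals[intervals["mode"] == "refined"] if "mode" in intervals else intervals
    overall = size_fractions(refined["width"].to_numpy())
    per = (
        refined.groupby("chrom")["width"]
        .agg(n="size", mean_width_bp="mean")
        .reset_index()
    )
    if track is not None:
        rates = track.windows.groupby("chrom")["rate"].mean().rename("mean_rate")
        per = per.merge(rates, on="chrom", how="left")
    return SizeSummary(
        overall["n"], overall["median_bp"], overall["frac_lt_2kb"], overall["frac_lt_5kb"], per
    )


def export_for_downstream(
    dataset: pd.DataFrame,
    binmap,
    counts: pd.Series,
    outdir: str,
    genome_fasta: str | None = None,
    features: FeatureSet | None = None,
    hotspots=None,
) -> dict[str, str]:
    """Write phenotype/genotype/sequence/gene-list files for external tools.

    Produces a per-individual crossover-count phenotype TSV, an R/qtl-style
    rotated genotype CSV, a FASTA of interval sequences (when a genome FASTA
    is supplied) and gene lists overlapping crossovers or inside hotspots
    (gene span + 1-kb TSS flank).
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    pheno = os.path.join(outdir, "crossover_counts.tsv")
    counts.rename("crossover_count").rename_axis("sample").reset_index().to_csv(
        pheno, sep="\t", index=False
    )
    paths["phenotypes"] = pheno
    if binmap is not None:
        from .io import write_qtl_csvr

        qtl = os.path.join(outdir, "qtl_genotypes.csv")
        write_qtl_csvr(binmap, counts, qtl)
        paths["qtl_csv"] = qtl
    if genome_fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(genome_fasta))
        out = os.path.join(outdir, "crossover_intervals.fasta")
        with open(out, "w") as fh:
            for k, row in enumerate(dataset.itertuples()):
                if row.right > len(fa[row.chrom]):
                    raise ValueError(f"interval beyond contig {row.chrom}")
                seq = fa[row.chrom][row.left : row.right].seq
                fh.write(f">xo{k + 1:05d} {row.chrom}:{row.left}-{row.right}\n{seq}\n")
        paths["fasta"] = out
    if features is not None and not features.genes.empty:
        hit_genes = _genes_touching(features.genes, features, dataset)
        out = os.path.join(outdir, "crossover_genes.txt")
        with open(out, "w") as fh:
            fh.write("\n".join(hit_genes) + ("\n" if hit_genes else ""))
        paths["crossover_genes"] = out
        if hotspots is not None:
            regions = hotspots.regions if hasattr(hotspots, "regions") else hotspots
            hot = _genes_touching(features.genes, features, regions.rename(columns={"start": "left", "end": "right"}))
            out = os.path.join(outdir, "hotspot_genes.txt")
            with open(out, "w") as fh:
                fh.write("\n".join(hot) + ("\n" if hot else ""))
            paths["hotspot_genes"] = out
    return paths


def _genes_touching(genes: pd.DataFrame, features: FeatureSet, intervals: pd.DataFrame) -> list[str]:
    """Gene IDs whose span or 1-kb TSS flank intersects any interval."""
    out = []
    by_chrom = {c: intervals[intervals["chrom"] == c] for c in intervals["chrom"].unique()}
    for g in genes.itertuples():
        sub = by_chrom.get(g.chrom)
        if sub is None or sub.empty:
            continue
        if g.strand == "+":
            s, e = g.start - 1000, g.end
        else:
            s, e = g.start, g.end + 1000
        if bool(
            np.any((sub["left"].to_numpy() < e) & (sub["right"].to_numpy() > max(s, 0)))
        ):
            out.append(g.gene_id)
    return out
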