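"""Readers and writers for the pipeline's file formats.

Phased SNPs and F2 genotypes travel as VCF v4.2 (GT + AD); annotation as
GFF3; TEs, repeats, SVs, crossovers and hotspots as BED (0-based half-open);
truth and summary tables as TSV.  VCF is read back through cyvcf2 and FASTA
through pyfaidx.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotyping import PhasedVariantSet, SNPGenotypeMatrix
from .simpop import SimTruth, ToyAnnotation, ToyGenome, generate_sequence

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "write_bed",
    "read_bed",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_genome_fasta",
    "write_qtl_csvr",
    "write_outputs",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(variants: PhasedVariantSet, matrix: SNPGenotypeMatrix | None, path, genome: ToyGenome | None = None) -> None:
    """VCF v4.2 with parent-A as REF, parent-B as ALT, and GT:AD per sample.

    GT is the hard call implied by the allele-depth ratio (the same rule the
    pipeline uses); AD carries the raw depths so callers can re-genotype.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    if genome is not None:
        for name, length in genome.chromosomes:
            lines.append(f"##contig=<ID={name},length={length}>")
    samples = matrix.samples if matrix is not None else []
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for chrom in variants.chrom_order:
            pos = variants.positions[chrom]
            ref = variants.allele_a[chrom]
            alt = variants.allele_b[chrom]
            if matrix is not None:
                calls = matrix.calls(chrom)
                da = matrix.depth_a[chrom]
                db = matrix.depth_b[chrom]
            for j in range(pos.size):
                fields = [chrom, str(int(pos[j])), ".", str(ref[j]), str(alt[j]), ".", "PASS", "."]
                if samples:
                    fields.append("GT:AD")
                    col = calls[:, j]
                    fields.extend(
                        f"{_GT.get(int(c), './.')}:{int(a)},{int(b)}"
                        for c, a, b in zip(col, da[:, j], db[:, j])
                    )
                fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[PhasedVariantSet, SNPGenotypeMatrix | None]:
    """Read a GT:AD VCF back into the pipeline's containers."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom_order: list[str] = []
    pos: dict[str, list[int]] = {}
    ra: dict[str, list[str]] = {}
    rb: dict[str, list[str]] = {}
    da: dict[str, list[np.ndarray]] = {}
    db: dict[str, list[np.ndarray]] = {}
    for rec in vcf:
        c = rec.CHROM
        if c not in pos:
            chrom_order.append(c)
            pos[c], ra[c], rb[c], da[c], db[c] = [], [], [], [], []
        pos[c].append(rec.POS)
        ra[c].append(rec.REF)
        rb[c].append(rec.ALT[0])
        if samples:
            ad = rec.format("AD")
            da[c].append(ad[:, 0].astype(np.int64))
            db[c].append(ad[:, 1].astype(np.int64))
    variants = PhasedVariantSet(
        chrom_order,
        {c: np.asarray(pos[c], dtype=np.int64) for c in chrom_order},
        {c: np.asarray(ra[c], dtype="U1") for c in chrom_order},
        {c: np.asarray(rb[c], dtype="U1") for c in chrom_order},
    )
    if not samples:
        return variants, None
    matrix = SNPGenotypeMatrix(
        variants,
        samples,
        {c: np.maximum(np.stack(da[c], axis=1), 0).astype(np.uint16) for c in chrom_order},
        {c: np.maximum(np.stack(db[c], axis=1), 0).astype(np.uint16) for c in chrom_order},
    )
    return variants, matrix


def write_gff3(annotation: ToyAnnotation, path) -> None:
    """Gene models (gene/mRNA/exon/UTR) as GFF3, 1-based inclusive."""
    ex_by_gene = {g: sub for g, sub in annotation.exons.groupby("gene_id")}
    u5 = {g: sub for g, sub in annotation.five_utr.groupby("gene_id")}
    u3 = {g: sub for g, sub in annotation.three_utr.groupby("gene_id")}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes.itertuples():
            base = (g.chrom, "xomap", "%s", str(g.start + 1), str(g.end), ".", g.strand, ".")

            def row(ftype, attrs, s=None, e=None):
                f = list(base)
                f[2] = ftype
                if s is not None:
                    f[3], f[4] = str(s + 1), str(e)
                f.append(attrs)
                return "\t".join(f) + "\n"

            fh.write(row("gene", f"ID={g.gene_id}"))
            mrna_id = f"{g.gene_id}.1"
            fh.write(row("mRNA", f"ID={mrna_id};Parent={g.gene_id}"))
            for part, ftype in ((ex_by_gene, "exon"), (u5, "five_prime_UTR"), (u3, "three_prime_UTR")):
                for r in part.get(g.gene_id, pd.DataFrame()).itertuples():
                    fh.write(row(ftype, f"Parent={mrna_id}", r.start, r.end))


def write_bed(df: pd.DataFrame, path, name_col: str | None = None, score_col: str | None = None, extra_cols: list[str] | None = None) -> None:
    """BED (0-based half-open) from a chrom/start/end DataFrame."""
    out = df[["chrom", "start", "end"]].copy() if "start" in df else df[["chrom", "left", "right"]].rename(columns={"left": "start", "right": "end"})
    out["name"] = df[name_col] if name_col else "."
    out["score"] = df[score_col] if score_col else 0
    out["strand"] = df["strand"] if "strand" in df else "."
    for col in extra_cols or []:
        out[col] = df[col].values
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def write_truth_tsv(truth: SimTruth, path) -> None:
    truth.crossovers[["individual", "sample", "chrom", "gamete", "pos"]].to_csv(
        path, sep="\t", index=False
    )


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genome_fasta(
    genome: ToyGenome, path, variants: PhasedVariantSet | None = None, seed: int = 0, width: int = 60
) -> None:
    """Deterministic random genome sequence (region-dependent GC; parent-A
    alleles at SNP positions) wrapped at ``width`` columns."""
    seqs = generate_sequence(genome, variants, seed)
    with open(path, "w") as fh:
        for chrom, _ in genome.chromosomes:
            fh.write(f">{chrom}\n")
            raw = seqs[chrom].tobytes().decode()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def write_qtl_csvr(binmap, phenotypes: pd.Series, path) -> None:
    """Rotated (csvr) genotype/phenotype layout for R/qtl-style tools.

    First row: the phenotype; then one row per bin marker with chromosome,
    position (Mb) and A/H/B/- genotype codes.
    """
    from .genotyping import geno_str

    samples = binmap.samples
    pheno = phenotypes.reindex(samples)
    with open(path, "w") as fh:
        fh.write("crossover_count,," + "," + ",".join(str(int(v)) for v in pheno) + "\n")
        for b in range(binmap.n_bins):
            row = binmap.bins.iloc[b]
            codes = [geno_str(c) if c >= 0 else "-" for c in binmap.genotypes[b]]
            marker = f"{row['chrom']}_bin{b + 1}"
            chrom_num = str(row["chrom"]).lstrip("chr").lstrip("0") or "1"
            pos_mb = (row["start"] + row["end"]) / 2 / 1e6
            fh.write(f"{marker},{chrom_num},{pos_mb:.4f}," + ",".join(codes) + "\n")


def write_outputs(
    outdir,
    genome: ToyGenome,
    annotation: ToyAnnotation,
    variants: PhasedVariantSet,
    matrix: SNPGenotypeMatrix | None = None,
    truth: SimTruth | None = None,
    svs: pd.DataFrame | None = None,
    fasta: bool = False,
    seed: int = 0,
) -> dict[str, str]:
    """Write the simulated study to disk (VCF, GFF3, BEDs, truth TSV)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    p = os.path.join(outdir, "population.vcf")
    write_vcf(variants, matrix, p, genome)
    paths["vcf"] = p
    p = os.path.join(outdir, "annotation.gff3")
    write_gff3(annotation, p)
    paths["gff3"] = p
    p = os.path.join(outdir, "tes.bed")
    write_bed(annotation.tes, p, extra_cols=["te_class"])
    paths["tes"] = p
    rep_rows = []
    for chrom in genome.names:
        s, e = annotation.repeat_set(chrom)
        rep_rows.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    p = os.path.join(outdir, "repeats.bed")
    write_bed(pd.DataFrame(rep_rows, columns=["chrom", "start", "end"]), p)
    paths["repeats"] = p
    if svs is not None:
        p = os.path.join(outdir, "svs.bed")
        write_bed(svs, p)
        paths["svs"] = p
    if truth is not None:
        p = os.path.join(outdir, "truth.tsv")
        write_truth_tsv(truth, p)
        paths["truth"] = p
    if fasta:
        p = os.path.join(outdir, "genome.fasta")
        write_genome_fasta(genome, p, variants, seed)
        paths["fasta"] = p
    return paths
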