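"""Genotype calling for F2 progeny from phased-SNP allele depths.

An F2 individual is coded against the two parental haplotypes: ``A`` (0) for
homozygous parent-A, ``H`` (1) for heterozygous, ``B`` (2) for homozygous
parent-B and ``NA`` (-1) where the evidence is insufficient.  Calls are made
at two granularities:

* per SNP, from the allele-depth ratio;
* per sliding window, either *physical* windows (pooled read counts, robust
  at 1.5-3x depth) or *snp_count* windows (majority vote over per-SNP calls,
  robust at ~14x depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GENO_A",
    "GENO_H",
    "GENO_B",
    "GENO_NA",
    "geno_str",
    "PhasedVariantSet",
    "SNPGenotypeMatrix",
    "WindowSpec",
    "WindowCall",
    "WindowGrid",
    "call_snp_genotypes",
    "window_calls",
    "window_genotype",
]

GENO_A, GENO_H, GENO_B, GENO_NA = 0, 1, 2, -1
_GENO_STR = {GENO_A: "A", GENO_H: "H", GENO_B: "B", GENO_NA: "NA"}


def geno_str(code: int) -> str:
    return _GENO_STR[int(code)]


@dataclass
class PhasedVariantSet:
    """Phased biallelic SNPs: positions (1-based) plus parental alleles.

    ``positions[chrom]`` is strictly increasing; ``allele_a``/``allele_b``
    hold the parent-A (reference) and parent-B bases and differ at every site.
    """

    chrom_order: list[str]
    positions: dict[str, np.ndarray]
    allele_a: dict[str, np.ndarray]
    allele_b: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom in self.chrom_order:
            pos = self.positions[chrom]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: SNP positions not strictly increasing")
            if np.any(self.allele_a[chrom] == self.allele_b[chrom]):
                raise ValueError(f"{chrom}: parental alleles identical at some site")

    def n_snps(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return sum(int(self.positions[c].size) for c in self.chrom_order)


@dataclass
class SNPGenotypeMatrix:
    """Per-individual, per-SNP allele depths for a phased variant set.

    ``depth_a[chrom]`` and ``depth_b[chrom]`` are (N individuals x S SNPs)
    integer arrays of reads supporting the parent-A and parent-B allele.
    """

    variants: PhasedVariantSet
    samples: list[str]
    depth_a: dict[str, np.ndarray]
    depth_b: dict[str, np.ndarray]
    _call_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def calls(
        self,
        chrom: str,
        min_depth: int = 3,
        hom_max: float = 0.1,
        het_band: tuple[float, float] = (0.25, 0.75),
    ) -> np.ndarray:
        """Per-SNP genotype codes (N x S int8), cached per parameter set."""
        key = (chrom, min_depth, hom_max, het_band)
        if key not in self._call_cache:
            self._call_cache[key] = call_snp_genotypes(
                self.depth_a[chrom], self.depth_b[chrom], min_depth, hom_max, het_band
            )
        return self._call_cache[key]


def call_snp_genotypes(
    depth_a,
    depth_b,
    min_depth: int = 3,
    hom_max: float = 0.1,
    het_band: tuple[float, float] = (0.25, 0.75),
) -> np.ndarray:
    """Call A/H/B/NA from allele depths.

    With d = depth_a + depth_b: NA if d < min_depth; A if depth_b/d <= hom_max;
    B if depth_a/d <= hom_max; H if depth_a/d falls in ``het_band``; otherwise
    NA.  The gaps between ``hom_max`` and the het band are deliberate dead
    zones that map to NA rather than flip-flopping between calls.
    """
    depth_a = np.asarray(depth_a)
    depth_b = np.asarray(depth_b)
    if np.any(depth_a < 0) or np.any(depth_b < 0):
        raise ValueError("negative allele depths")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = depth_a + depth_b
    calls = np.full(depth_a.shape, GENO_NA, dtype=np.int8)
    ok = total >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(total > 0, depth_a / np.maximum(total, 1), 0.0)
    calls[ok & (1.0 - frac_a <= hom_max)] = GENO_A
    calls[ok & (frac_a <= hom_max)] = GENO_B
    lo, hi = het_band
    calls[ok & (frac_a >= lo) & (frac_a <= hi)] = GENO_H
    return calls


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window definition: ``physical`` (bp) or ``snp_count`` units."""

    mode: str
    size: int
    step: int

    def __post_init__(self):
        if self.mode not in ("physical", "snp_count"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if not (self.size >= self.step >= 1):
            raise ValueError("require size >= step >= 1")


#: the coarse grid used to genotype whole individuals (1 Mb / 100 kb)
COARSE_SPEC = WindowSpec("physical", 1_000_000, 100_000)
#: the fine grid used inside refinement regions (15 SNPs / 1 SNP)
FINE_SPEC = WindowSpec("snp_count", 15, 1)


@dataclass(frozen=True)
class WindowCall:
    chrom: str
    start: int
    end: int
    call: int
    n_snps: int
    depth_a: int
    depth_b: int


@dataclass
class WindowGrid:
    """Window calls for all individuals on one chromosome."""

    chrom: str
    starts: np.ndarray  # 0-based half-open window bounds
    ends: np.ndarray
    calls: np.ndarray  # (N individuals x W windows) int8
    n_snps: np.ndarray  # informative SNPs per window (physical: all SNPs)
    depth_a: np.ndarray | None = None  # pooled depths (physical mode only)
    depth_b: np.ndarray | None = None


def _physical_grid(length: int, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, spec.step, dtype=np.int64)
    ends = np.minimum(starts + spec.size, length)
    return starts, ends


def _pooled_window_calls(
    matrix: SNPGenotypeMatrix,
    chrom: str,
    spec: WindowSpec,
    length: int,
    min_reads: int,
    a_min: float,
    b_max: float,
    het_band: tuple[float, float],
) -> WindowGrid:
    pos0 = matrix.variants.positions[chrom] - 1  # 0-based
    starts, ends = _physical_grid(length, spec)
    da = matrix.depth_a[chrom]
    db = matrix.depth_b[chrom]
    ca = np.concatenate((np.zeros((da.shape[0], 1), dtype=np.int64), np.cumsum(da, axis=1)), axis=1)
    cb = np.concatenate((np.zeros((db.shape[0], 1), dtype=np.int64), np.cumsum(db, axis=1)), axis=1)
    i0 = np.searchsorted(pos0, starts, side="left")
    i1 = np.searchsorted(pos0, ends, side="left")
    wa = ca[:, i1] - ca[:, i0]
    wb = cb[:, i1] - cb[:, i0]
    total = wa + wb
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(total > 0, wa / np.maximum(total, 1), 0.0)
    calls = np.full(total.shape, GENO_NA, dtype=np.int8)
    ok = total >= min_reads
    calls[ok & (frac_a >= a_min)] = GENO_A
    calls[ok & (frac_a <= b_max)] = GENO_B
    lo, hi = het_band
    calls[ok & (frac_a >= lo) & (frac_a <= hi)] = GENO_H
    return WindowGrid(chrom, starts, ends, calls, (i1 - i0).astype(np.int64), wa, wb)


def _vote_window_calls(
    snp_calls: np.ndarray,
    pos: np.ndarray,
    chrom: str,
    spec: WindowSpec,
    min_informative: int,
    min_agreement: float,
) -> WindowGrid:
    n, s = snp_calls.shape
    if s < 1:
        z = np.empty(0, dtype=np.int64)
        return WindowGrid(chrom, z, z.copy(), np.empty((n, 0), dtype=np.int8), z.copy())
    size, step = spec.size, spec.step
    w_first = np.arange(0, max(s - size, 0) + 1, step, dtype=np.int64)
    if w_first.size == 0:  # fewer SNPs than one window: single truncated window
        w_first = np.array([0], dtype=np.int64)
    w_last = np.minimum(w_first + size, s)
    onehot = [
        np.concatenate(
            (np.zeros((n, 1), dtype=np.int32), np.cumsum(snp_calls == g, axis=1, dtype=np.int32)),
            axis=1,
        )
        for g in (GENO_A, GENO_H, GENO_B)
    ]
    counts = np.stack([c[:, w_last] - c[:, w_first] for c in onehot])  # (3, N, W)
    informative = counts.sum(axis=0)
    best = counts.max(axis=0)
    calls = counts.argmax(axis=0).astype(np.int8)
    bad = (informative < min_informative) | (best < min_agreement * np.maximum(informative, 1))
    calls[bad] = GENO_NA
    starts = pos[w_first] - 1
    ends = pos[w_last - 1]  # 1-based inclusive last SNP == 0-based half-open end
    return WindowGrid(chrom, starts, ends, calls, (w_last - w_first).astype(np.int64), None, None)


def window_calls(
    matrix: SNPGenotypeMatrix,
    chrom: str,
    spec: WindowSpec,
    chrom_length: int | None = None,
    min_reads: int = 10,
    a_min: float = 0.9,
    b_max: float = 0.1,
    het_band: tuple[float, float] = (0.25, 0.75),
    min_informative: int = 8,
    min_agreement: float = 0.8,
    snp_call_kwargs: dict | None = None,
) -> WindowGrid:
    """Window genotype calls for every individual on one chromosome.

    Physical windows pool allele depths and apply ratio thresholds
    (A: frac_a >= ``a_min``; B: frac_a <= ``b_max``; H inside ``het_band``;
    otherwise NA, also NA below ``min_reads`` pooled reads).  SNP-count
    windows take a majority vote over non-missing per-SNP calls, requiring
    ``min_informative`` informative SNPs and ``min_agreement`` agreement.
    """
    if spec.mode == "physical":
        if chrom_length is None:
            pos = matrix.variants.positions[chrom]
            chrom_length = int(pos[-1]) if pos.size else 0
        return _pooled_window_calls(
            matrix, chrom, spec, chrom_length, min_reads, a_min, b_max, het_band
        )
    snp_calls = matrix.calls(chrom, **(snp_call_kwargs or {}))
    return _vote_window_calls(
        snp_calls, matrix.variants.positions[chrom], chrom, spec, min_informative, min_agreement
    )


def window_genotype(
    matrix: SNPGenotypeMatrix,
    spec: WindowSpec,
    sample: str,
    chrom_lengths: dict[str, int] | None = None,
    **kwargs,
) -> list[WindowCall]:
    """Window calls for one individual across all chromosomes, in order."""
    idx = matrix.samples.index(sample)
    out: list[WindowCall] = []
    for chrom in matrix.variants.chrom_order:
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        grid = window_calls(matrix, chrom, spec, chrom_length=length, **kwargs)
        da = grid.depth_a[idx] if grid.depth_a is not None else np.zeros(grid.starts.size, int)
        db = grid.depth_b[idx] if grid.depth_b is not None else np.zeros(grid.starts.size, int)
        for w in range(grid.starts.size):
            out.append(
                WindowCall(
                    chrom,
                    int(grid.starts[w]),
                    int(grid.ends[w]),
                    int(grid.calls[idx, w]),
                    int(grid.n_snps[w]),
                    int(da[w]),
                    int(db[w]),
                )
            )
    return out
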