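"""Population bin maps and segregation-distortion testing.

Each chromosome is partitioned at the union of all individuals' crossover
midpoints, so every individual's genotype is constant within a bin by
construction; adjacent bins with identical genotype vectors are merged.
Each bin's A/H/B counts are tested against the Mendelian F2 expectation
1:2:1 with a chi-square goodness-of-fit test (df = 2); bins with raw
P < 0.001 are flagged as segregation-distorted, with no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import GENO_A, GENO_B, GENO_H, GENO_NA
from .simpop import ToyGenome
from .xodetect import XoResult

__all__ = ["BinMap", "build_binmap", "segregation_distortion", "distortion_summary"]


def segregation_distortion(n_a: int, n_h: int, n_b: int, alpha: float = 0.001):
    """Chi-square 1:2:1 test on non-missing calls.

    Returns (chi2, P, distorted flag); (nan, nan, None) for an all-NA bin.
    """
    n = n_a + n_h + n_b
    if n == 0:
        return float("nan"), float("nan"), None
    expected = np.array([n / 4, n / 2, n / 4])
    chi2 = float(np.sum((np.array([n_a, n_h, n_b]) - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, p, p < alpha


@dataclass
class BinMap:
    """Bin coordinates with the per-individual genotype matrix."""

    bins: pd.DataFrame  # chrom, start, end, n_a, n_h, n_b, chi2, p, distorted
    genotypes: np.ndarray  # (n_bins x N) int8 codes
    samples: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def distorted_length(self) -> int:
        sel = self.bins["distorted"].fillna(False).astype(bool)
        return int((self.bins.loc[sel, "end"] - self.bins.loc[sel, "start"]).sum())


def build_binmap(
    result: XoResult, genome: ToyGenome, alpha: float = 0.001, merge_identical: bool = True
) -> BinMap:
    """Bin map from detected crossovers (boundaries at interval midpoints)."""
    rows = []
    geno_rows = []
    samples = result.samples
    for chrom in result.chrom_order:
        length = genome.lengths[chrom]
        sub = result.intervals[result.intervals["chrom"] == chrom]
        mids = np.unique(np.round(sub["midpoint"].to_numpy()).astype(np.int64))
        mids = mids[(mids > 0) & (mids < length)]
        edges = np.concatenate(([0], mids, [length]))
        starts, ends = edges[:-1], edges[1:]
        centres = (starts + ends) / 2.0
        geno = np.full((starts.size, len(samples)), GENO_NA, dtype=np.int8)
        for s_idx, sample in enumerate(samples):
            bounds, segs = result.paints[(sample, chrom)]
            geno[:, s_idx] = segs[np.searchsorted(bounds, centres, side="right")]
        if merge_identical and starts.size > 1:
            same = np.all(geno[1:] == geno[:-1], axis=1)
            keep = np.concatenate(([True], ~same))
            block = np.cumsum(keep) - 1
            new_starts = starts[keep]
            new_ends = np.array(
                [ends[block == b].max() for b in range(block[-1] + 1)], dtype=np.int64
            )
            geno = geno[keep]
            starts, ends = new_starts, new_ends
        for b in range(starts.size):
            rows.append((chrom, int(starts[b]), int(ends[b])))
            geno_rows.append(geno[b])
    genotypes = np.asarray(geno_rows, dtype=np.int8)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["n_a"] = (genotypes == GENO_A).sum(axis=1)
    bins["n_h"] = (genotypes == GENO_H).sum(axis=1)
    bins["n_b"] = (genotypes == GENO_B).sum(axis=1)
    tested = [segregation_distortion(a, h, b, alpha) for a, h, b in zip(bins["n_a"], bins["n_h"], bins["n_b"])]
    bins["chi2"] = [t[0] for t in tested]
    bins["p"] = [t[1] for t in tested]
    bins["distorted"] = [t[2] for t in tested]
    return BinMap(bins, genotypes, list(samples))


def distortion_summary(binmap: BinMap, genome: ToyGenome) -> dict:
    """Population-level distortion summary (bin counts, Mb and % of genome)."""
    distorted = binmap.bins["distorted"].fillna(False).astype(bool)
    mb = binmap.distorted_length() / 1e6
    total = genome.total_length()
    return {
        "n_bins": binmap.n_bins,
        "n_distorted": int(distorted.sum()),
        "distorted_mb": mb,
        "distorted_pct": 100.0 * binmap.distorted_length() / total,
    }
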