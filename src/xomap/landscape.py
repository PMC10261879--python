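"""Windowed recombination rates, hotspots, suppression and correlations.

The per-window rate is ``WinRcRate = WinCoCounts / N * 100`` centimorgans,
where ``WinCoCounts`` counts crossovers whose interval midpoint falls in the
window and ``N`` is the number of individuals; the genome-wide rate is
``GenomeRcRate = sum(WinCoCounts) / (WinCounts * N) * 100``, i.e. the mean of
the window rates over all windows (truncated terminal windows included).
Hotspots are merged runs of windows at or above a rate threshold (the study
scales: 12 cM/2 Mb coarse, 2.4 cM/50 kb fine); suppression calling looks for
runs of euchromatic low-rate windows with adequate SNP density and annotates
them with any supplied structural-variant intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .simpop import ToyAnnotation, ToyGenome
from .xodetect import XoResult

__all__ = [
    "RateTrack",
    "HotspotSet",
    "SuppressionReport",
    "window_rates",
    "fold_change",
    "call_hotspots",
    "shared_hotspots",
    "suppression_scan",
    "snp_density_track",
    "feature_density_tracks",
    "correlations",
    "CorrelationReport",
]


@dataclass
class RateTrack:
    """Windowed crossover counts and rates (cM) for one population."""

    windows: pd.DataFrame  # chrom, start, end, count, rate
    n_individuals: int
    size: int
    step: int
    population: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def genome_rate(self) -> float:
        """GenomeRcRate = sum(WinCoCounts) / (WinCounts * N) * 100."""
        return float(self.windows["count"].sum()) / (self.n_windows * self.n_individuals) * 100.0


def _window_grid(length: int, size: int, step: int):
    starts = np.arange(0, length, step, dtype=np.int64)
    ends = np.minimum(starts + size, length)
    return starts, ends


def window_rates(
    crossovers: pd.DataFrame | XoResult,
    genome: ToyGenome,
    n_individuals: int,
    size: int = 2_000_000,
    step: int = 1_000_000,
    population: str = "",
) -> RateTrack:
    """Windowed crossover counts/rates; a crossover is assigned to every
    window containing its interval midpoint."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    intervals = crossovers.intervals if isinstance(crossovers, XoResult) else crossovers
    rows = []
    for chrom, length in genome.chromosomes:
        mids = np.sort(intervals.loc[intervals["chrom"] == chrom, "midpoint"].to_numpy())
        starts, ends = _window_grid(length, size, step)
        counts = np.searchsorted(mids, ends, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(c)))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    windows["rate"] = windows["count"] / n_individuals * 100.0
    return RateTrack(windows, n_individuals, size, step, population)


def fold_change(threshold: float, genome_rate: float) -> float:
    """Fold of a hotspot threshold over the genome-wide rate."""
    if genome_rate <= 0:
        raise ValueError("genome rate must be positive")
    return threshold / genome_rate


@dataclass
class HotspotSet:
    """Merged above-threshold windows with per-hotspot peak rate."""

    regions: pd.DataFrame  # chrom, start, end, peak_rate, fold
    threshold: float
    genome_rate: float
    scale: str = ""

    @property
    def threshold_fold(self) -> float:
        return fold_change(self.threshold, self.genome_rate)

    def per_chrom(self, chrom: str):
        sub = self.regions[self.regions["chrom"] == chrom]
        return iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())


def call_hotspots(track: RateTrack, threshold: float, scale: str = "") -> HotspotSet:
    """Merge overlapping/adjacent windows with rate >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    win = track.windows
    for chrom in win["chrom"].unique():
        sub = win[(win["chrom"] == chrom) & (win["rate"] >= threshold)]
        if sub.empty:
            continue
        ms, me = iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        for s, e in zip(ms, me):
            inside = sub[(sub["start"] >= s) & (sub["end"] <= e)]
            peak = float(inside["rate"].max())
            rows.append((chrom, int(s), int(e), peak, peak / track.genome_rate))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_rate", "fold"])
    return HotspotSet(regions, threshold, track.genome_rate, scale)


def shared_hotspots(
    hotspot_sets: list[HotspotSet], min_populations: int | None = None
) -> pd.DataFrame:
    """Regions covered by hotspots in >= min_populations populations."""
    if len(hotspot_sets) < 2:
        raise ValueError("shared hotspots need at least two populations")
    k = len(hotspot_sets) if min_populations is None else min_populations
    chroms: set[str] = set()
    for hs in hotspot_sets:
        chroms |= set(hs.regions["chrom"])
    rows = []
    for chrom in sorted(chroms):
        sets = [hs.per_chrom(chrom) for hs in hotspot_sets]
        ms, me = iv.coverage_at_least(sets, k)
        for s, e in zip(ms, me):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class SuppressionReport:
    """Euchromatic suppression calls and low-SNP-density false-positive flags."""

    suppressed: pd.DataFrame  # chrom, start, end, n_windows, sv_overlap
    low_snp_flags: pd.DataFrame  # chrom, start, end  (excluded from calls)


def snp_density_track(variants, track: RateTrack) -> np.ndarray:
    """SNPs per window, aligned with ``track.windows`` rows."""
    counts = np.zeros(len(track.windows), dtype=np.int64)
    for chrom in track.windows["chrom"].unique():
        mask = (track.windows["chrom"] == chrom).to_numpy()
        pos0 = variants.positions[chrom] - 1
        s = track.windows.loc[mask, "start"].to_numpy()
        e = track.windows.loc[mask, "end"].to_numpy()
        counts[mask] = np.searchsorted(pos0, e) - np.searchsorted(pos0, s)
    return counts


def suppression_scan(
    track: RateTrack,
    genome: ToyGenome,
    snp_counts: np.ndarray,
    sv_intervals: pd.DataFrame | None = None,
    low_rate: float = 0.5,
    min_run: int = 3,
    min_snp_per_100kb: float = 10.0,
) -> SuppressionReport:
    """Find runs of low-rate euchromatic windows.

    Windows below the SNP-density floor are flagged as false-positive
    candidates instead of contributing to suppression calls.  Each
    suppression region is annotated with overlapping (>= 1 bp) SV intervals.
    """
    win = track.windows
    sup_rows, fp_rows = [], []
    for chrom in genome.names:
        mask = (win["chrom"] == chrom).to_numpy()
        sub = win[mask]
        if sub.empty:
            continue
        eu = genome.euchromatin(chrom)
        centres = ((sub["start"] + sub["end"]) // 2).to_numpy()
        in_eu = iv.points_in(*eu, centres)
        dens_ok = snp_counts[mask] >= min_snp_per_100kb * (
            (sub["end"] - sub["start"]).to_numpy() / 1e5
        )
        low = (sub["rate"].to_numpy() <= low_rate) & in_eu
        for s, e in zip(sub["start"].to_numpy()[low & ~dens_ok], sub["end"].to_numpy()[low & ~dens_ok]):
            fp_rows.append((chrom, int(s), int(e)))
        candidate = low & dens_ok
        # runs of >= min_run consecutive candidate windows
        run_start = None
        idx = np.arange(candidate.size)
        for i in np.concatenate((idx, [candidate.size])):
            if i < candidate.size and candidate[i]:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start >= min_run:
                    s = int(sub["start"].to_numpy()[run_start])
                    e = int(sub["end"].to_numpy()[i - 1])
                    sup_rows.append((chrom, s, e, int(i - run_start)))
                run_start = None
    suppressed = pd.DataFrame(sup_rows, columns=["chrom", "start", "end", "n_windows"])
    sv_overlap = []
    for _, row in suppressed.iterrows():
        hits = []
        if sv_intervals is not None:
            sel = sv_intervals[
                (sv_intervals["chrom"] == row["chrom"])
                & (sv_intervals["start"] < row["end"])
                & (sv_intervals["end"] > row["start"])
            ]
            hits = [f"{r.chrom}:{r.start}-{r.end}" for r in sel.itertuples()]
        sv_overlap.append(",".join(hits))
    suppressed["sv_overlap"] = sv_overlap
    return SuppressionReport(suppressed, pd.DataFrame(fp_rows, columns=["chrom", "start", "end"]))


def feature_density_tracks(
    track: RateTrack,
    genome: ToyGenome,
    annotation: ToyAnnotation | None = None,
    variants=None,
    sequences: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-window covariate densities aligned with the rate track.

    Columns (when inputs are given): gene_density and repeat/class I/class II
    TE densities as bp fractions, snp_density as SNPs per window, gc as G+C
    fraction from the supplied sequences.
    """
    win = track.windows
    out = pd.DataFrame(index=win.index)
    lengths = (win["end"] - win["start"]).to_numpy()
    per_chrom_cache: dict[str, dict] = {}
    for chrom in win["chrom"].unique():
        sets = {}
        if annotation is not None:
            g = annotation.genes[annotation.genes["chrom"] == chrom]
            sets["gene_density"] = iv.merge(g["start"].to_numpy(), g["end"].to_numpy())
            sets["repeat_density"] = annotation.repeat_set(chrom)
            sets["classI_density"] = annotation.te_set(chrom, "I")
            sets["classII_density"] = annotation.te_set(chrom, "II")
        per_chrom_cache[chrom] = sets
    if annotation is not None:
        for col in ("gene_density", "repeat_density", "classI_density", "classII_density"):
            vals = np.zeros(len(win))
            for chrom in win["chrom"].unique():
                mask = (win["chrom"] == chrom).to_numpy()
                s = win.loc[mask, "start"].to_numpy()
                e = win.loc[mask, "end"].to_numpy()
                vals[mask] = iv.overlap_bp(*per_chrom_cache[chrom][col], s, e)
            out[col] = vals / lengths
    if variants is not None:
        out["snp_density"] = snp_density_track(variants, track) / lengths * 1e5  # per 100 kb
    if sequences is not None:
        gc = np.zeros(len(win))
        for chrom in win["chrom"].unique():
            mask = (win["chrom"] == chrom).to_numpy()
            seq = sequences[chrom]
            is_gc = np.concatenate(([0], np.cumsum((seq == b"G") | (seq == b"C"))))
            s = win.loc[mask, "start"].to_numpy()
            e = win.loc[mask, "end"].to_numpy()
            gc[mask] = is_gc[e] - is_gc[s]
        out["gc"] = gc / lengths
    return out


@dataclass
class CorrelationReport:
    """Crossover-count and window-rate correlation tables."""

    chrom_level: pd.DataFrame  # variable, r, p  (count vs chrom/euchromatin length)
    window_level: pd.DataFrame  # feature, r, p  (rate vs covariate density)
    method: str


def correlations(
    track: RateTrack,
    feature_densities: pd.DataFrame,
    counts_by_chrom: pd.Series,
    genome: ToyGenome,
    method: str = "pearson",
) -> CorrelationReport:
    """Correlate per-chromosome crossover counts with chromosome/euchromatin
    length, and window rates with covariate densities."""
    if method == "pearson":
        corr = stats.pearsonr
    elif method == "spearman":
        corr = stats.spearmanr
    else:
        raise ValueError(f"unknown method {method!r}")
    chroms = [c for c in genome.names if c in counts_by_chrom.index]
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes for chromosome-level correlation")
    counts = counts_by_chrom.loc[chroms].to_numpy(dtype=float)
    rows = []
    for label, x in (
        ("chromosome_length", np.array([genome.lengths[c] for c in chroms], dtype=float)),
        ("euchromatin_length", np.array([genome.euchromatin_length(c) for c in chroms], dtype=float)),
    ):
        r, p = corr(x, counts)
        rows.append((label, float(r), float(p)))
    chrom_level = pd.DataFrame(rows, columns=["variable", "r", "p"])
    wrows = []
    rates = track.windows["rate"].to_numpy(dtype=float)
    for col in feature_densities.columns:
        y = feature_densities[col].to_numpy(dtype=float)
        if len(y) < 3:
            raise ValueError("need >= 3 windows for window-level correlation")
        r, p = corr(rates, y)
        wrows.append((col, float(r), float(p)))
    window_level = pd.DataFrame(wrows, columns=["feature", "r", "p"])
    return CorrelationReport(chrom_level, window_level, method)
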