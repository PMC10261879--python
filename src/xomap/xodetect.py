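"""Two-stage crossover detection in F2 individuals.

Stage 1 (coarse): genotype each individual on overlapping physical windows
(default 1 Mb / 100 kb), collapse consecutive identical calls into segments
(NA windows are transparent) and place a candidate breakpoint at the middle
position of the two adjacent windows whose genotype changes, flanked by the
anchor bins Bin_A and Bin_H.

Stage 2 (refine): re-genotype the SNPs between the two bins with 15-SNP /
1-SNP windows, then tighten the breakpoint to the two closest informative
SNPs: the right endpoint is the first SNP of the first run of ``anchor_w``
consecutive calls matching the new genotype, and the left endpoint is the
last concordant call of the old genotype before it (preferring calls with an
adjacent concordant neighbour, which resists isolated genotyping errors).

Low-depth populations skip stage 2 (``mode="coarse"``): the reported
interval is the region between the flanking window edges, centred on the
candidate midpoint.  Direct A<->B segment adjacency -- impossible in a
single meiotic event -- is emitted as two stacked crossovers flagged
``double``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import (
    COARSE_SPEC,
    FINE_SPEC,
    GENO_A,
    GENO_B,
    GENO_H,
    GENO_NA,
    SNPGenotypeMatrix,
    WindowGrid,
    WindowSpec,
    geno_str,
    window_calls,
)
from .simpop import ToyGenome

__all__ = [
    "CandidateBreakpoint",
    "XoResult",
    "coarse_breakpoints",
    "refine_interval",
    "detect_crossovers",
]


@dataclass(frozen=True)
class CandidateBreakpoint:
    """A coarse breakpoint between two anchor bins of differing genotype."""

    sample: str
    chrom: str
    midpoint: float
    a_start: int
    a_end: int
    a_geno: int
    a_widx: int
    h_start: int
    h_end: int
    h_geno: int
    h_widx: int


def _segments(calls_row: np.ndarray) -> list[tuple[int, int, int]]:
    """(genotype, first window idx, last window idx) runs, skipping NA."""
    idx = np.flatnonzero(calls_row != GENO_NA)
    segs: list[tuple[int, int, int]] = []
    for i in idx:
        g = int(calls_row[i])
        if segs and segs[-1][0] == g:
            segs[-1] = (g, segs[-1][1], int(i))
        else:
            segs.append((g, int(i), int(i)))
    return segs


def coarse_breakpoints(grid: WindowGrid, calls_row: np.ndarray, sample: str) -> list[CandidateBreakpoint]:
    """Candidate breakpoints for one individual on one chromosome.

    Candidates whose anchor bins share a window (a single-window middle
    segment) are collapsed: into one A<->B-style candidate when the outer
    genotypes differ, or dropped as a spurious blip when they match.
    """
    segs = _segments(calls_row)
    cands: list[CandidateBreakpoint] = []
    for (g_l, _, last_l), (g_r, first_r, _) in zip(segs, segs[1:]):
        cands.append(
            CandidateBreakpoint(
                sample,
                grid.chrom,
                (float(grid.ends[last_l]) + float(grid.starts[first_r])) / 2.0,
                int(grid.starts[last_l]),
                int(grid.ends[last_l]),
                g_l,
                last_l,
                int(grid.starts[first_r]),
                int(grid.ends[first_r]),
                g_r,
                first_r,
            )
        )
    out: list[CandidateBreakpoint] = []
    i = 0
    while i < len(cands):
        c = cands[i]
        if i + 1 < len(cands) and cands[i + 1].a_widx == c.h_widx:
            nxt = cands[i + 1]
            if c.a_geno != nxt.h_geno:
                merged = CandidateBreakpoint(
                    c.sample,
                    c.chrom,
                    (c.midpoint + nxt.midpoint) / 2.0,
                    c.a_start,
                    c.a_end,
                    c.a_geno,
                    c.a_widx,
                    nxt.h_start,
                    nxt.h_end,
                    nxt.h_geno,
                    nxt.h_widx,
                )
                out.append(merged)
            # same outer genotype: one-window blip, treated as noise
            i += 2
            continue
        out.append(c)
        i += 1
    return out


def _first_anchor_run(calls: np.ndarray, geno: int, w: int) -> int | None:
    """Index of the first position starting w consecutive calls == geno."""
    hit = calls == geno
    if hit.size < w:
        return None
    run = np.ones(hit.size - w + 1, dtype=bool)
    for k in range(w):
        run &= hit[k : hit.size - w + 1 + k]
    pos = np.flatnonzero(run)
    return int(pos[0]) if pos.size else None


class RefinementFailure(Exception):
    """No usable genotype transition inside the refinement region."""


def refine_interval(
    candidate: CandidateBreakpoint,
    snp_calls_row: np.ndarray,
    positions: np.ndarray,
    anchor_w: int = 3,
    fine_spec: WindowSpec = FINE_SPEC,
    min_informative: int = 8,
    min_agreement: float = 0.8,
    depth_a_row: np.ndarray | None = None,
    depth_b_row: np.ndarray | None = None,
    boundary_min_depth: int = 12,
) -> tuple[int, int]:
    """Tighten a candidate to its two flanking SNP positions (1-based).

    When allele depths are supplied, a homozygous call may serve as an
    interval *endpoint* only if its depth makes an undercalled heterozygote
    implausible (total >= ``boundary_min_depth`` with zero opposite-allele
    reads); unqualified endpoints step outward to the nearest qualified
    call, which can only widen the interval.  Raises
    :class:`RefinementFailure` when the region shows no transition from the
    candidate's old to its new genotype.
    """
    pos0 = positions - 1
    lo = min(candidate.a_start, candidate.h_start)
    hi = max(candidate.a_end, candidate.h_end)
    region = np.flatnonzero((pos0 >= lo) & (pos0 < hi))
    calls = snp_calls_row[region]
    informative = calls != GENO_NA
    inf_idx = region[informative]
    inf_calls = calls[informative]
    from_g, to_g = candidate.a_geno, candidate.h_geno
    if inf_calls.size == 0:
        raise RefinementFailure("no informative SNPs in region")
    if inf_calls.size >= fine_spec.size:
        # stage-2 gate: 15-SNP window genotypes must actually change
        win = _vote_sequence(inf_calls, fine_spec, min_informative, min_agreement)
        win = win[win != GENO_NA]
        if not _has_transition(win, from_g, to_g):
            raise RefinementFailure("no window-level genotype change in region")
    if depth_a_row is not None and depth_b_row is not None:
        da = depth_a_row[inf_idx].astype(np.int64)
        db = depth_b_row[inf_idx].astype(np.int64)
        minor = np.where(inf_calls == GENO_A, db, np.where(inf_calls == GENO_B, da, 0))
        qual = (inf_calls == GENO_H) | ((da + db >= boundary_min_depth) & (minor == 0))
    else:
        qual = np.ones(inf_calls.size, dtype=bool)
    j0 = _first_anchor_run(inf_calls, to_g, anchor_w)
    if j0 is None or j0 == 0:
        raise RefinementFailure("new genotype not anchored in region")
    after = np.flatnonzero((inf_calls == to_g) & qual)
    after = after[after >= j0]
    j = int(after[0]) if after.size else j0
    before = np.flatnonzero(inf_calls[:j0] == from_g)
    if before.size == 0:
        raise RefinementFailure("old genotype absent before the new-genotype anchor")
    neigh = np.zeros(inf_calls.size, dtype=bool)
    neigh[1:] |= inf_calls[1:] == inf_calls[:-1]
    neigh[:-1] |= inf_calls[:-1] == inf_calls[1:]
    for mask in (neigh[before] & qual[before], qual[before], neigh[before]):
        picked = before[mask]
        if picked.size:
            i = int(picked[-1])
            break
    else:
        i = int(before[-1])
    return int(positions[inf_idx[i]]), int(positions[inf_idx[j]])


def _vote_sequence(inf_calls, spec, min_informative, min_agreement):
    n = inf_calls.size
    w = n - spec.size + 1
    counts = np.zeros((3, w), dtype=np.int32)
    for g in range(3):
        c = np.concatenate(([0], np.cumsum(inf_calls == g)))
        counts[g] = c[spec.size :] - c[: w]
    informative = counts.sum(axis=0)
    best = counts.max(axis=0)
    seq = counts.argmax(axis=0).astype(np.int8)
    seq[(informative < min_informative) | (best < min_agreement * np.maximum(informative, 1))] = (
        GENO_NA
    )
    return seq


def _has_transition(seq: np.ndarray, from_g: int, to_g: int) -> bool:
    """True if from_g occurs before to_g in the (NA-free) call sequence."""
    to_pos = np.flatnonzero(seq == to_g)
    if to_pos.size == 0:
        return False
    return bool(np.any(np.flatnonzero(seq == from_g) < to_pos[-1]))


@dataclass
class XoResult:
    """Detected crossovers for a population."""

    intervals: pd.DataFrame
    samples: list[str]
    chrom_order: list[str]
    paints: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    # paints[(sample, chrom)] = (midpoint boundaries, segment genotype codes)

    def counts_per_individual(self) -> pd.Series:
        c = self.intervals.groupby("sample").size()
        return c.reindex(self.samples, fill_value=0)

    def counts_by_chrom(self) -> pd.DataFrame:
        tab = self.intervals.groupby(["sample", "chrom"]).size().unstack(fill_value=0)
        return tab.reindex(index=self.samples, columns=self.chrom_order, fill_value=0)


def _resolution_class(width: float) -> str:
    if width < 2000:
        return "<2kb"
    if width < 5000:
        return "<5kb"
    return ">=5kb"


def detect_crossovers(
    matrix: SNPGenotypeMatrix,
    genome: ToyGenome,
    mode: str = "refined",
    coarse_spec: WindowSpec = COARSE_SPEC,
    anchor_w: int = 3,
    fine_spec: WindowSpec = FINE_SPEC,
    min_pooled_reads: int = 10,
    snp_call_kwargs: dict | None = None,
) -> XoResult:
    """Detect crossover intervals for every individual.

    ``mode="refined"`` runs the coarse stage then SNP-level refinement (for
    ~14x populations); ``mode="coarse"`` reports the window-bounded interval
    around each candidate midpoint (for 1.5-3x populations).  Candidates
    whose refinement fails are retained with their coarse interval.
    """
    if mode not in ("refined", "coarse"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    paints: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    step = coarse_spec.step
    for chrom in matrix.variants.chrom_order:
        grid = window_calls(
            matrix,
            chrom,
            coarse_spec,
            chrom_length=genome.lengths[chrom],
            min_reads=min_pooled_reads,
        )
        snp_calls = matrix.calls(chrom, **(snp_call_kwargs or {})) if mode == "refined" else None
        positions = matrix.variants.positions[chrom]
        for s_idx, sample in enumerate(matrix.samples):
            calls_row = grid.calls[s_idx]
            cands = coarse_breakpoints(grid, calls_row, sample)
            mids, genos = [], []

            def _coarse_bounds(cand):
                lo, hi = sorted((cand.a_end, cand.h_start))
                if lo == hi:
                    lo = int(cand.midpoint - step / 2)
                    hi = int(cand.midpoint + step / 2)
                return lo, hi

            last_h = [GENO_NA]

            def _emit(cand, lo, hi, used_mode):
                double = abs(cand.a_geno - cand.h_geno) == 2  # A<->B
                midpoint = (lo + hi) / 2.0
                width = hi - lo
                last_h[0] = cand.h_geno
                for _ in range(2 if double else 1):
                    rows.append(
                        (
                            sample,
                            chrom,
                            int(lo),
                            int(hi),
                            geno_str(cand.a_geno),
                            geno_str(cand.h_geno),
                            int(width),
                            midpoint,
                            _resolution_class(width),
                            used_mode,
                            double,
                        )
                    )
                mids.append(midpoint)
                genos.append(cand.a_geno)

            k = 0
            while k < len(cands):
                cand = cands[k]
                lo, hi = _coarse_bounds(cand)
                if mode != "refined":
                    _emit(cand, lo, hi, "coarse")
                    k += 1
                    continue
                try:
                    lo, hi = refine_interval(
                        cand,
                        snp_calls[s_idx],
                        positions,
                        anchor_w,
                        fine_spec,
                        depth_a_row=matrix.depth_a[chrom][s_idx],
                        depth_b_row=matrix.depth_b[chrom][s_idx],
                    )
                    _emit(cand, lo, hi, "refined")
                    k += 1
                    continue
                except RefinementFailure:
                    pass
                # a sharp A<->B flip shows an artifact H band in pooled
                # windows; try the merged outer-to-outer transition
                if k + 1 < len(cands):
                    nxt = cands[k + 1]
                    if nxt.a_geno == cand.h_geno and nxt.h_geno != cand.a_geno:
                        merged = CandidateBreakpoint(
                            sample,
                            chrom,
                            (cand.midpoint + nxt.midpoint) / 2.0,
                            cand.a_start,
                            cand.a_end,
                            cand.a_geno,
                            cand.a_widx,
                            nxt.h_start,
                            nxt.h_end,
                            nxt.h_geno,
                            nxt.h_widx,
                        )
                        try:
                            mlo, mhi = refine_interval(
                                merged,
                                snp_calls[s_idx],
                                positions,
                                anchor_w,
                                fine_spec,
                                depth_a_row=matrix.depth_a[chrom][s_idx],
                                depth_b_row=matrix.depth_b[chrom][s_idx],
                            )
                            _emit(merged, mlo, mhi, "refined")
                            k += 2
                            continue
                        except RefinementFailure:
                            pass
                _emit(cand, lo, hi, "coarse")
                k += 1
            if genos:
                genos.append(last_h[0])
            else:
                segs = _segments(calls_row)
                genos.append(segs[0][0] if segs else GENO_NA)
            bounds = np.asarray(mids, dtype=float)
            order = np.argsort(bounds, kind="stable")
            paints[(sample, chrom)] = (
                bounds[order],
                np.asarray(genos, dtype=np.int8)[np.concatenate((order, [len(mids)]))],
            )
    intervals = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "left",
            "right",
            "from_geno",
            "to_geno",
            "width",
            "midpoint",
            "res_class",
            "mode",
            "double",
        ],
    )
    return XoResult(intervals, list(matrix.samples), list(matrix.variants.chrom_order), paints)
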