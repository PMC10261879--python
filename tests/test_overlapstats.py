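"""Feature derivation, overlap rates, interval-size summaries and the
Monte Carlo enrichment null."""

import numpy as np
import pandas as pd
import pytest

from xomap import (
    FeatureSet,
    derive_features,
    filter_high_resolution,
    monte_carlo_null,
    overlap_rates,
    size_fractions,
    summarize_sizes,
)
from xomap.simpop import ToyAnnotation, ToyGenome


def _genome(lengths):
    chroms = [(f"chr{i + 1:02d}", l) for i, l in enumerate(lengths)]
    return ToyGenome(chroms, {n: (l // 2, l // 2) for n, l in chroms})


def _feature_set(genome, per_chrom):
    sets = {}
    for cls, spans in per_chrom.items():
        sets[cls] = {
            c: (np.array([s for s, _ in spans.get(c, [])], dtype=np.int64),
                np.array([e for _, e in spans.get(c, [])], dtype=np.int64))
            for c in genome.names
        }
    return FeatureSet(genome.lengths, sets)


class TestFilterHighResolution:
    def test_strictly_below_cutoff(self):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "left": [0, 0, 0],
                "right": [500, 4999, 5000],
                "width": [500, 4999, 5000],
                "mode": "refined",
                "double": False,
            }
        )
        out = filter_high_resolution(df)
        assert list(out["width"]) == [500, 4999]

    def test_double_flagged_events_excluded(self):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "left": [0, 0],
                "right": [100, 100],
                "width": [100, 100],
                "mode": "refined",
                "double": [True, False],
            }
        )
        assert len(filter_high_resolution(df)) == 1

    def test_empty_input_empty_output(self):
        df = pd.DataFrame(columns=["chrom", "left", "right", "width", "mode", "double"])
        assert filter_high_resolution(df).empty

    def test_printed_size_fractions(self):
        # the study's composition: 2205 < 2 kb, 2457 < 5 kb, of 3140
        widths = np.concatenate(
            (np.full(2205, 1000), np.full(2457 - 2205, 3000), np.full(3140 - 2457, 8000))
        )
        frac = size_fractions(widths)
        assert round(100 * frac["frac_lt_2kb"], 1) == 70.2
        assert round(100 * frac["frac_lt_5kb"], 2) == 78.25


class TestDeriveFeatures:
    def test_plus_strand_flanks(self):
        genome = _genome([10_000])
        ann = ToyAnnotation(
            pd.DataFrame([("chr01", 1000, 2000, "+", "g1")], columns=["chrom", "start", "end", "strand", "gene_id"]),
            pd.DataFrame([("g1", "chr01", 1000, 2000)], columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["chrom", "start", "end", "te_class"]),
            pd.DataFrame(columns=["chrom", "start", "end"]),
        )
        feats = derive_features(ann, genome)
        assert [tuple(x) for x in zip(*feats.get("tss_u1k", "chr01"))] == [(0, 1000)]
        assert [tuple(x) for x in zip(*feats.get("tts_d1k", "chr01"))] == [(2000, 3000)]
        # single-exon gene: no introns; intergenic = complement of the gene
        assert feats.get("intron", "chr01")[0].size == 0
        assert [tuple(x) for x in zip(*feats.get("intergenic", "chr01"))] == [(0, 1000), (2000, 10_000)]

    def test_minus_strand_flank_is_reversed(self):
        genome = _genome([10_000])
        ann = ToyAnnotation(
            pd.DataFrame([("chr01", 1000, 2000, "-", "g1")], columns=["chrom", "start", "end", "strand", "gene_id"]),
            pd.DataFrame([("g1", "chr01", 1000, 2000)], columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            pd.DataFrame(columns=["chrom", "start", "end", "te_class"]),
            pd.DataFrame(columns=["chrom", "start", "end"]),
        )
        feats = derive_features(ann, genome)
        assert [tuple(x) for x in zip(*feats.get("tss_u1k", "chr01"))] == [(2000, 3000)]
        assert [tuple(x) for x in zip(*feats.get("tts_d1k", "chr01"))] == [(0, 1000)]

    def test_introns_are_gene_minus_exons(self, default_study):
        feats = derive_features(default_study.annotation, default_study.genome)
        from xomap import _intervals as iv

        for chrom in default_study.genome.names:
            gene = feats.get("gene", chrom)
            exon = feats.get("exon", chrom)
            intron = feats.get("intron", chrom)
            assert iv.total_length(*gene) == iv.total_length(*exon) + iv.total_length(*intron)
            assert iv.total_length(*iv.intersect(exon, intron)) == 0


class TestOverlapRates:
    def test_one_bp_overlap_counts(self):
        genome = _genome([1000])
        feats = _feature_set(genome, {"gene": {"chr01": [(250, 900)]}})
        df = pd.DataFrame({"chrom": ["chr01"], "left": [100], "right": [300]})
        out = overlap_rates(df, feats, classes=["gene"])
        assert out.loc[out["feature"] == "gene", "count"].iloc[0] == 1

    def test_printed_count_identity(self):
        # gene 1403 + intergenic 1631 - both 577 = 2457 intervals
        assert 1403 + 1631 - 577 == 2457
        assert round(1403 / 2457 * 100, 1) == 57.1
        assert round(1631 / 2457 * 100, 1) == 66.4
        assert round(577 / 2457 * 100, 1) == 23.5

    def test_coverage_identity_on_random_intervals(self, rng):
        """gene + intergenic - both == total whenever the two classes tile
        the genome, for arbitrary interval sets."""
        genome = _genome([100_000, 60_000])
        for _ in range(20):
            spans = {}
            for c, l in genome.chromosomes:
                cuts = np.sort(rng.choice(np.arange(1000, l - 1000), 6, replace=False))
                spans[c] = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, 6, 2)]
            feats = _feature_set(genome, {"gene": spans})
            from xomap import _intervals as iv

            feats.sets["intergenic"] = {
                c: iv.complement(*feats.get("gene", c), genome.lengths[c]) for c in genome.names
            }
            n = 40
            chrom = rng.choice(genome.names, n)
            left = np.array([rng.integers(0, genome.lengths[c] - 500) for c in chrom])
            df = pd.DataFrame({"chrom": chrom, "left": left, "right": left + rng.integers(1, 500, n)})
            out = overlap_rates(df, feats, classes=["gene", "intergenic"]).set_index("feature")
            assert (
                out.loc["gene", "count"]
                + out.loc["intergenic", "count"]
                - out.loc["gene_and_intergenic", "count"]
                == n
            )


class TestMonteCarloNull:
    def test_full_coverage_gives_p_one(self):
        genome = _genome([50_000])
        feats = _feature_set(genome, {"gene": {"chr01": [(0, 50_000)]}})
        df = pd.DataFrame({"chrom": ["chr01"] * 5, "left": [0, 10, 20, 30, 40], "right": [5, 15, 25, 35, 45]})
        out = monte_carlo_null(df, feats, genome, m=200, seed=1, classes=["gene"])
        row = out.table.iloc[0]
        assert row["observed_pct"] == 100.0 and row["null_mean_pct"] == 100.0
        assert row["p"] == 1.0

    def test_half_coverage_null_near_50pct(self):
        """Features covering half of every chromosome: the null overlap rate
        is ~50% (+O(len/chrom)) -- within 3 SD at M=1000."""
        genome = _genome([200_000, 100_000])
        feats = _feature_set(
            genome, {"gene": {"chr01": [(0, 100_000)], "chr02": [(0, 50_000)]}}
        )
        n = 100
        df = pd.DataFrame({"chrom": ["chr01"] * n, "left": np.arange(n) * 10, "right": np.arange(n) * 10 + 200})
        out = monte_carlo_null(df, feats, genome, m=1000, seed=2, classes=["gene"])
        row = out.table.iloc[0]
        assert abs(row["null_mean_pct"] - 50.0) < 3 * row["null_sd_pct"] + 1.0

    def test_determinism_under_fixed_seed(self, default_study, default_result):
        feats = derive_features(default_study.annotation, default_study.genome)
        hires = filter_high_resolution(default_result.intervals)
        a = monte_carlo_null(hires, feats, default_study.genome, m=200, seed=7)
        b = monte_carlo_null(hires, feats, default_study.genome, m=200, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_p_bounds(self, default_study, default_result):
        feats = derive_features(default_study.annotation, default_study.genome)
        hires = filter_high_resolution(default_result.intervals)
        m = 150
        out = monte_carlo_null(hires, feats, default_study.genome, m=m, seed=9)
        assert (out.table["p"] >= 1 / (m + 1)).all()
        assert (out.table["p"] <= 1.0).all()

    def test_null_calibration_is_super_uniform(self):
        """Observed intervals drawn from the null placement reject at most
        at the nominal level."""
        genome = _genome([150_000, 100_000])
        feats = _feature_set(
            genome, {"gene": {"chr01": [(10_000, 60_000)], "chr02": [(20_000, 50_000)]}}
        )
        rng = np.random.default_rng(12)
        alpha = 0.05
        rejections = 0
        reps = 200
        chrom_lens = np.array([l for _, l in genome.chromosomes])
        p_chrom = chrom_lens / chrom_lens.sum()
        for _ in range(reps):
            n = 40
            lengths = rng.integers(50, 400, n)
            ci = rng.choice(2, n, p=p_chrom)
            starts = (rng.random(n) * (chrom_lens[ci] - lengths)).astype(int)
            df = pd.DataFrame(
                {
                    "chrom": np.array(genome.names)[ci],
                    "left": starts,
                    "right": starts + lengths,
                }
            )
            out = monte_carlo_null(df, feats, genome, m=500, seed=rng, classes=["gene"])
            rejections += out.table["p"].iloc[0] <= alpha
        # the guarantee is on the expected rate; allow binomial noise
        assert rejections / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_oversized_interval_rejected(self):
        genome = _genome([10_000])
        feats = _feature_set(genome, {"gene": {"chr01": [(0, 100)]}})
        df = pd.DataFrame({"chrom": ["chr01"], "left": [0], "right": [20_000]})
        with pytest.raises(ValueError):
            monte_carlo_null(df, feats, genome, m=10, seed=0, classes=["gene"])

    def test_invalid_replicate_count_rejected(self, default_study):
        feats = _feature_set(_genome([1000]), {"gene": {"chr01": [(0, 10)]}})
        df = pd.DataFrame({"chrom": ["chr01"], "left": [0], "right": [5]})
        with pytest.raises(ValueError):
            monte_carlo_null(df, feats, _genome([1000]), m=0, seed=0)


class TestSummarizeSizes:
    def test_median_and_fractions(self):
        df = pd.DataFrame(
            {"chrom": "c", "width": [100, 700, 900], "mode": "refined"}
        )
        s = summarize_sizes(df)
        assert s.median_bp == 700
        df = pd.DataFrame({"chrom": "c", "width": [1000, 3000], "mode": "refined"})
        s = summarize_sizes(df)
        assert (s.frac_lt_2kb, s.frac_lt_5kb) == (0.5, 1.0)

    def test_per_chromosome_counts_conserve_total(self, default_result):
        s = summarize_sizes(default_result.intervals)
        assert s.per_chrom["n"].sum() == s.n

    def test_empty_input(self):
        s = summarize_sizes(pd.DataFrame(columns=["chrom", "width", "mode"]))
        assert s.n == 0 and np.isnan(s.median_bp)
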