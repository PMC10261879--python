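"""Recombination-rate formulas, hotspot/suppression calling and the
correlation analyses."""

import numpy as np
import pandas as pd
import pytest

from xomap import (
    CrossoverModel,
    RateLandscape,
    SimConfig,
    call_hotspots,
    correlations,
    detect_crossovers,
    feature_density_tracks,
    fold_change,
    shared_hotspots,
    simulate_f2,
    simulate_genome,
    snp_density_track,
    suppression_scan,
    window_rates,
)
from xomap.landscape import HotspotSet, RateTrack
from xomap.simpop import ToyGenome


def _xo_df(midpoints, chrom="chr01"):
    return pd.DataFrame(
        {
            "sample": "s1",
            "chrom": chrom,
            "left": np.asarray(midpoints, dtype=int) - 1,
            "right": np.asarray(midpoints, dtype=int) + 1,
            "midpoint": midpoints,
        }
    )


def _genome(lengths):
    chroms = [(f"chr{i + 1:02d}", l) for i, l in enumerate(lengths)]
    return ToyGenome(chroms, {n: (l // 2, l // 2) for n, l in chroms})


class TestWindowRates:
    def test_rate_formula(self):
        # WinCoCounts = 8, N = 200 -> WinRcRate = 4 cM
        track = window_rates(_xo_df([500_000.0] * 8), _genome([4_000_000]), 200)
        assert track.windows["rate"].iloc[0] == pytest.approx(8 / 200 * 100)

    def test_midpoint_counted_in_every_covering_window(self):
        # size 2 Mb step 1 Mb: a crossover at 1.55 Mb hits [0,2) and [1,3)
        track = window_rates(_xo_df([1_550_000.0]), _genome([6_000_000]), 10)
        w = track.windows
        hit = w[w["count"] > 0]
        assert [(s, e) for s, e in zip(hit["start"], hit["end"])] == [
            (0, 2_000_000),
            (1_000_000, 3_000_000),
        ]
        assert w["count"].sum() == 2

    def test_zero_crossovers_zero_rates(self):
        track = window_rates(_xo_df([]), _genome([4_000_000]), 10)
        assert (track.windows["rate"] == 0).all()
        assert track.genome_rate == 0.0

    def test_genome_rate_equals_mean_window_rate(self, resolvable_study, resolvable_result):
        track = window_rates(
            resolvable_result, resolvable_study.genome, resolvable_study.config.n_individuals
        )
        assert track.genome_rate == pytest.approx(track.windows["rate"].mean())

    def test_interior_crossover_counted_in_size_over_step_windows(self):
        track = window_rates(_xo_df([3_500_000.0]), _genome([8_000_000]), 10)
        assert track.windows["count"].sum() == track.size // track.step

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            window_rates(_xo_df([]), _genome([4_000_000]), 0)


class TestHotspots:
    def test_printed_threshold_folds(self):
        # the five study populations: threshold 12 cM/2 Mb over mean rates
        means = {"Upotato 1": 3.58, "RH": 3.71, "PG6359": 3.78, "C10-20": 3.06, "D43-7": 3.58}
        folds = {k: round(fold_change(12.0, v), 2) for k, v in means.items()}
        assert folds == {
            "Upotato 1": 3.35,
            "RH": 3.23,
            "PG6359": 3.17,
            "C10-20": 3.92,
            "D43-7": 3.35,
        }

    def test_fine_scale_threshold_fold_rounds_to_29(self):
        assert round(fold_change(2.4, 0.084)) == 29

    def test_hotspot_windows_merge_and_respect_threshold(self):
        track = window_rates(_xo_df([2_500_000.0] * 30 + [3_300_000.0] * 25), _genome([10_000_000]), 100)
        hs = call_hotspots(track, threshold=20.0)
        assert len(hs.regions) == 1
        region = hs.regions.iloc[0]
        win = track.windows
        inside = win[(win["start"] >= region["start"]) & (win["end"] <= region["end"])]
        assert (inside["rate"] >= 20.0).all()
        assert region["peak_rate"] == win["rate"].max()
        # maximality: the windows just outside are below threshold
        outside = win[(win["end"] == region["start"]) | (win["start"] == region["end"])]
        assert (outside["rate"] < 20.0).all()

    def test_uniformly_cold_track_has_no_hotspots(self):
        track = window_rates(_xo_df([500_000.0]), _genome([4_000_000]), 100)
        assert call_hotspots(track, threshold=12.0).regions.empty

    def test_threshold_validation(self):
        track = window_rates(_xo_df([]), _genome([4_000_000]), 10)
        with pytest.raises(ValueError):
            call_hotspots(track, threshold=0.0)


def _hs(regions, chrom="chr01"):
    df = pd.DataFrame(regions, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["peak_rate"] = 1.0
    df["fold"] = 1.0
    return HotspotSet(df, 12.0, 4.0)


class TestSharedHotspots:
    def test_identical_hotspots_are_shared(self):
        shared = shared_hotspots([_hs([(10, 20)]), _hs([(10, 20)])])
        assert list(shared.itertuples(index=False)) == [("chr01", 10, 20)]

    def test_disjoint_hotspots_share_nothing(self):
        assert shared_hotspots([_hs([(10, 20)]), _hs([(30, 40)])], min_populations=2).empty

    def test_region_common_to_all_five_populations(self):
        sets = [_hs([(1_000_000, 3_000_000), (5_000_000 + i * 100_000, 6_000_000 + i * 100_000)]) for i in range(5)]
        shared = shared_hotspots(sets, min_populations=5)
        assert len(shared) >= 1
        assert (shared.iloc[0]["start"], shared.iloc[0]["end"]) == (1_000_000, 3_000_000)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            shared_hotspots([_hs([(0, 10)])])


@pytest.fixture(scope="module")
def inversion_study():
    cfg = SimConfig(n_individuals=80, chrom_lengths=(8_000_000,), seed=77)
    genome, annotation, variants = simulate_genome(cfg)
    # the inversion must span at least one whole 2 Mb window to be visible
    # at the default window scale
    inversion = [(5_500_000, 8_000_000)]
    land = RateLandscape.for_genome(
        genome, pericentromere_factor=0.02, suppressed={"chr01": inversion}
    )
    matrix, truth = simulate_f2(genome, variants, land, cfg)
    res = detect_crossovers(matrix, genome, mode="refined")
    track = window_rates(res, genome, cfg.n_individuals)
    return genome, variants, track, inversion


class TestSuppression:
    def test_inversion_shows_up_as_sv_overlapping_suppression(self, inversion_study):
        genome, variants, track, inversion = inversion_study
        svs = pd.DataFrame(
            [("chr01", s, e) for s, e in inversion], columns=["chrom", "start", "end"]
        )
        report = suppression_scan(
            track,
            genome,
            snp_density_track(variants, track),
            sv_intervals=svs,
            low_rate=0.2 * track.genome_rate,
            min_run=1,
        )
        sup = report.suppressed
        hit = sup[(sup["start"] < inversion[0][1]) & (sup["end"] > inversion[0][0])]
        assert not hit.empty
        assert (hit["sv_overlap"] != "").any()

    def test_low_snp_density_is_flagged_not_called(self, inversion_study):
        genome, variants, track, _ = inversion_study
        report = suppression_scan(
            track,
            genome,
            np.zeros(len(track.windows), dtype=np.int64),  # no SNPs anywhere
            low_rate=0.2 * track.genome_rate,
            min_run=1,
        )
        assert report.suppressed.empty
        assert not report.low_snp_flags.empty

    def test_uniform_landscape_reports_nothing(self, resolvable_study, resolvable_result):
        study = resolvable_study
        track = window_rates(resolvable_result, study.genome, study.config.n_individuals)
        report = suppression_scan(
            track,
            study.genome,
            snp_density_track(study.variants, track),
            low_rate=0.05 * track.genome_rate,
            min_run=3,
        )
        assert report.suppressed.empty


class TestCorrelations:
    def test_perfect_and_inverted_tracks(self):
        genome = _genome([4_000_000, 5_000_000, 6_000_000])
        track = window_rates(_xo_df([1_000_000.0, 1_500_000.0]), genome, 10)
        dens = pd.DataFrame({"same": track.windows["rate"], "neg": -track.windows["rate"]})
        counts = pd.Series([1.0, 2.0, 3.0], index=genome.names)
        rep = correlations(track, dens, counts, genome)
        by_feat = rep.window_level.set_index("feature")["r"]
        assert by_feat["same"] == pytest.approx(1.0)
        assert by_feat["neg"] == pytest.approx(-1.0)

    def test_gene_driven_landscape_reproduces_sign_pattern(self):
        """Crossover intensity proportional to gene density yields a
        positive rate-gene and negative rate-repeat correlation."""
        cfg = SimConfig(
            n_individuals=60,
            chrom_lengths=(8_000_000, 6_000_000, 5_000_000, 4_000_000),
            seed=55,
        )
        genome, annotation, variants = simulate_genome(cfg)
        gene_sets = {
            c: (
                annotation.genes.loc[annotation.genes["chrom"] == c, "start"].to_numpy(),
                annotation.genes.loc[annotation.genes["chrom"] == c, "end"].to_numpy(),
            )
            for c in genome.names
        }
        land = RateLandscape.from_feature_density(genome, gene_sets, base=0.05, boost=3.0)
        matrix, truth = simulate_f2(genome, variants, land, cfg)
        res = detect_crossovers(matrix, genome, mode="refined")
        track = window_rates(res, genome, cfg.n_individuals)
        dens = feature_density_tracks(track, genome, annotation, variants)
        rep = correlations(track, dens, res.counts_by_chrom().sum(axis=0), genome)
        r = rep.window_level.set_index("feature")["r"]
        assert r["gene_density"] > 0
        assert r["repeat_density"] < 0
        assert r["classI_density"] < 0
        assert r["snp_density"] > 0
        # longer chromosomes accumulate more crossovers
        assert rep.chrom_level.set_index("variable").loc["chromosome_length", "r"] > 0
        assert rep.chrom_level.set_index("variable").loc["euchromatin_length", "r"] > 0

    def test_too_few_chromosomes_rejected(self):
        genome = _genome([4_000_000])
        track = window_rates(_xo_df([]), genome, 10)
        with pytest.raises(ValueError):
            correlations(track, pd.DataFrame({"x": track.windows["rate"]}), pd.Series([1.0], index=genome.names), genome)
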