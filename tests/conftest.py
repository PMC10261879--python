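"""Shared simulated-population fixtures.

The *resolvable* fixtures enforce a minimum separation between crossovers
(and a landscape margin at chromosome ends) so that every simulated event is
individually resolvable by the 1 Mb coarse windows; they are the ground for
exact oracle checks.  The *default* fixture keeps the unrestricted study
conditions.
"""

import numpy as np
import pytest

from xomap import (
    CrossoverModel,
    RateLandscape,
    SimConfig,
    detect_crossovers,
    simulate_f2,
    simulate_genome,
)
from xomap.simpop import SimStudy


def _make_study(config, margin=0, **landscape_kwargs):
    genome, annotation, variants = simulate_genome(config)
    landscape = RateLandscape.for_genome(genome, margin=margin, **landscape_kwargs)
    matrix, truth = simulate_f2(genome, variants, landscape, config)
    return SimStudy(config, genome, annotation, variants, landscape, matrix, truth)


@pytest.fixture(scope="session")
def resolvable_study():
    """50 deep-sequenced individuals, crossovers >= 2.6 Mb apart."""
    cfg = SimConfig(
        n_individuals=50,
        chrom_lengths=(6_000_000,) * 2,
        seed=101,
        min_separation=2_600_000,
    )
    return _make_study(cfg, margin=1_200_000)


@pytest.fixture(scope="session")
def resolvable_result(resolvable_study):
    return detect_crossovers(resolvable_study.matrix, resolvable_study.genome, mode="refined")


@pytest.fixture(scope="session")
def default_study():
    """Unrestricted study conditions at a small scale (40 individuals)."""
    cfg = SimConfig(n_individuals=40, chrom_lengths=(6_000_000, 4_000_000), seed=202)
    return _make_study(cfg, pericentromere_factor=0.02)


@pytest.fixture(scope="session")
def default_result(default_study):
    return detect_crossovers(default_study.matrix, default_study.genome, mode="refined")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
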