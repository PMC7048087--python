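"""Shared fixtures: desk-scale genomes and reusable simulated cohorts.

Session-scoped so the expensive simulations run once per test session.
"""

import numpy as np
import pytest

import ctdnakit as ck
from ctdnakit import aneuploidy as an
from ctdnakit import cna


@pytest.fixture(scope="session")
def genome2():
    """Two 50-Mb chromosomes, 1-kb GC windows — the CNA workhorse."""
    return ck.build_genome_model(2, 50_000_000, 1000, seed=7)


@pytest.fixture(scope="session")
def genome8():
    """Eight 20-Mb chromosomes (16 arms) for aneuploidy scoring."""
    return ck.build_genome_model(8, 20_000_000, 10_000, seed=3)


@pytest.fixture(scope="session")
def tiny_genome():
    """One 3-Mb chromosome for unit-scale tests."""
    return ck.build_genome_model(1, 3_000_000, 1000, seed=1)


@pytest.fixture(scope="session")
def balanced_scna(genome2):
    """10-Mb one-copy loss + 10-Mb one-copy gain: zero net coverage
    shift, so segment log2R is offset-free for dilution-law checks."""
    return (
        ck.SCNASegment("chr1", 0, 10_000_000, 1),
        ck.SCNASegment("chr2", 0, 10_000_000, 3),
    )


@pytest.fixture(scope="session")
def rcc_like_scna(genome2):
    """Arm-scale losses/gains covering ~75% of the genome, mimicking the
    multi-arm SCNA burden of a renal tumor (3p-/3q+/8p- style)."""
    b1 = genome2.arm_boundaries["chr1"]
    b2 = genome2.arm_boundaries["chr2"]
    return (
        ck.SCNASegment("chr1", 0, b1, 1),
        ck.SCNASegment("chr1", b1, 50_000_000, 3),
        ck.SCNASegment("chr2", 0, b2, 1),
    )


@pytest.fixture(scope="session")
def cna_controls(genome2):
    """Six healthy controls at 400k fragments with GC bias + jitter."""
    tmpl = ck.SimulationConfig(seed=0, n_fragments=400_000, gc_bias_strength=0.3)
    return ck.simulate_control_cohort(6, tmpl, genome2, seed=40)


@pytest.fixture(scope="session")
def prepared_cna_controls(cna_controls, genome2):
    return cna.prepare_controls(
        cna_controls, genome2, bin_bp=500_000, downsample_n=300_000, seed=11
    )


@pytest.fixture(scope="session")
def arm_controls(genome8):
    """46 healthy controls at 100k fragments with arm counts and the
    leave-one-out z matrix."""
    tmpl = ck.SimulationConfig(seed=0, n_fragments=100_000, gc_bias_strength=0.2)
    cohort = ck.simulate_control_cohort(46, tmpl, genome8, seed=50)
    counts = [an.arm_read_counts(c, genome8) for c in cohort]
    loo = an._loo_zscore_matrix(counts)
    return counts, loo


def make_profile(track, values, rng=None, sigma=0.0):
    """Build a NormalizedProfile with given per-usable-bin values."""
    log2r = np.full(track.n_bins, np.nan)
    excl = track.base_excluded.copy()
    ok = ~excl
    y = np.asarray(values, dtype=float)[: ok.sum()]
    if sigma > 0:
        y = y + rng.normal(0, sigma, len(y))
    log2r[ok] = y
    return cna.NormalizedProfile(track=track, log2r=log2r, excluded=excl, mode="control")
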