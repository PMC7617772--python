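"""Shared fixtures: planted synthetic datasets reused across the suite."""

import numpy as np
import pytest

from invrad import (
    GenomicRegion,
    genotype_region,
    polarize,
    rephase_by_inversion,
    simulate_cross,
    simulate_radiation,
)
from invrad.cli import default_scenario, scenario_from_dict

#: Planted inversion span of the default scenario.
PLANTED_REGION = GenomicRegion("chr1", 2_000_001, 5_000_000)

#: Suppressed region of the pedigree cross.
CROSS_REGION = GenomicRegion("chr1", 3_000_001, 7_000_000)


@pytest.fixture(scope="session")
def default_sim():
    """Two ingroup clades + outgroup, one inversion at frequency 0.5, seed 1."""
    return simulate_radiation(scenario_from_dict(default_scenario(1)))


@pytest.fixture(scope="session")
def outgroup_samples(default_sim):
    _, meta, _ = default_sim
    return meta.samples_for("clade", "outgroup")


@pytest.fixture(scope="session")
def ingroup_samples(default_sim, outgroup_samples):
    ds, _, _ = default_sim
    return [s for s in ds.sample_ids if s not in outgroup_samples]


@pytest.fixture(scope="session")
def inversion_call(default_sim, outgroup_samples):
    ds, _, _ = default_sim
    return genotype_region(
        ds, PLANTED_REGION, outgroup_samples=outgroup_samples, seed=1
    )


@pytest.fixture(scope="session")
def polarized_dataset(default_sim, outgroup_samples):
    ds, _, _ = default_sim
    return polarize(ds, outgroup_samples)


@pytest.fixture(scope="session")
def phased_region(default_sim, inversion_call):
    ds, _, _ = default_sim
    return rephase_by_inversion(ds, PLANTED_REGION, inversion_call)


@pytest.fixture(scope="session")
def cross_sim():
    """290-style pedigree: 100 F2 + 50 F3, suppression in CROSS_REGION."""
    length = 10_000_000
    positions = np.arange(10_000, length, 10_000)
    fa = np.zeros(len(positions), dtype=np.int8)
    fb = np.full(len(positions), 2, dtype=np.int8)
    return simulate_cross(
        fa, fb, 100, 50, positions, length,
        recomb_rate=2e-8, suppressed_region=CROSS_REGION, seed=7,
    )


@pytest.fixture(scope="session")
def quartet_scenario_factory():
    """Four-population (((P1,P2),P3),O) scenarios for D-statistic tests."""

    def make(seed, introgression=False, length=10_000_000):
        d = {
            "clades": [{"name": n, "n": 8, "ne": 10000} for n in ("P1", "P2", "P3", "O")],
            "splits": [
                {"time": 10000, "derived": ["P1", "P2"], "ancestral": "A12", "ne": 10000},
                {"time": 20000, "derived": ["A12", "P3"], "ancestral": "A123", "ne": 10000},
                {"time": 40000, "derived": ["A123", "O"], "ancestral": "root", "ne": 10000},
            ],
            "chromosomes": [{"name": "chr1", "length": length}],
            "seed": seed,
        }
        if introgression:
            d["introgressions"] = [
                {"time": 1000, "donor": "P3", "recipient": "P2", "fraction": 0.1}
            ]
        return scenario_from_dict(d)

    return make


@pytest.fixture(scope="session")
def conditioned_scenario_factory():
    """Star radiation of 8 ingroup species + P3 clade + outgroup, one inversion.

    ``transfer=False``: inversion states assigned independently of the tree
    (4 ingroup species inverted), no gene flow. ``transfer=True``: only S1
    shares the inverted state with P3 and also received a 15% genome-wide
    admixture pulse from P3.
    """

    def make(seed, transfer=False):
        ingroup = [f"S{i}" for i in range(1, 9)]
        inverted = ["S1"] if transfer else ["S1", "S2", "S3", "S4"]
        freqs = {s: 1.0 for s in inverted}
        freqs["P3"] = 1.0
        d = {
            "clades": [{"name": s, "n": 6, "ne": 10000} for s in ingroup]
            + [{"name": "P3", "n": 8, "ne": 10000}, {"name": "OUT", "n": 8, "ne": 10000}],
            "splits": [
                {"time": 3000, "derived": ingroup, "ancestral": "ING", "ne": 10000},
                {"time": 20000, "derived": ["ING", "P3"], "ancestral": "A1", "ne": 10000},
                {"time": 40000, "derived": ["A1", "OUT"], "ancestral": "root", "ne": 10000},
            ],
            "chromosomes": [
                {"name": "chr1", "length": 8_000_000},
                {"name": "chr2", "length": 8_000_000},
            ],
            "inversions": [
                {"chrom": "chr1", "start": 2_000_001, "end": 5_000_000,
                 "origin_time": 60000, "freqs": freqs}
            ],
            "outgroup_clades": ["OUT"],
            "seed": seed,
        }
        if transfer:
            d["introgressions"] = [
                {"time": 500, "donor": "P3", "recipient": "S1", "fraction": 0.15}
            ]
        return scenario_from_dict(d)

    return make
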