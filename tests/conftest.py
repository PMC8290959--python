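"""Shared fixtures: tiny deterministic cohorts and hand-built matrices."""

import numpy as np
import pytest

from soysweep.simulate import SimulationConfig, simulate_domestication
from soysweep.vcf_io import HaplotypeMatrix


def make_matrix(alleles, positions=None, chrom="chr1", phased=True, accessions=None):
    """HaplotypeMatrix from a (2n x m) 0/1/-1 array, SNP metadata filled in."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if accessions is None:
        accessions = [f"acc{i + 1}" for i in range(alleles.shape[0] // 2)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        is_indel=np.zeros(n_sites, dtype=bool),
        alleles=alleles,
        accessions=accessions,
        phased=phased,
    )


def random_matrix(rng, n_chrom=8, n_sites=30, spacing=50):
    """Random phased matrix with strictly increasing positions, no missing."""
    alleles = rng.integers(0, 2, size=(n_chrom, n_sites)).astype(np.int8)
    positions = np.cumsum(rng.integers(1, spacing, size=n_sites))
    return make_matrix(alleles, positions=positions)


@pytest.fixture(scope="session")
def small_config():
    """Desk-top simulation config: tiny but structurally faithful."""
    return SimulationConfig(
        n_ancestral=60,
        n_bottleneck=20,
        n_landrace=40,
        n_cultivar=60,
        t_split=40,
        t_bottleneck=10,
        t_total=100,
        n_sites=300,
        chrom_length_bp=150_000,
        sample_sizes={"S": 15, "L": 10, "C": 15},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_domestication(small_config)
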