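import numpy as np
import pytest

from woolgen.genotype import (
    GenotypeMatrix,
    make_sample_sheet,
    make_site_table,
)


def build_matrix(calls, populations, ploidy=None, chrom=None, pos=None,
                 ref=None, alt=None, roles=None):
    """Small-fixture helper: calls is (n_sites, n_samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if chrom is None:
        chrom = ["1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if ref is None:
        ref = ["A"] * n_sites
    if alt is None:
        alt = ["C"] * n_sites
    sites = make_site_table(chrom, pos, ref, alt)
    sample_ids = [f"s{j}" for j in range(n_samples)]
    samples = make_sample_sheet(sample_ids, populations, roles)
    return GenotypeMatrix(sites, samples, calls, ploidy)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_matrix(rng, n_sites=60, pops=("P1", "P1", "P2", "P3"),
                  missing_rate=0.1, haploid=False):
    """Random genotype fixture across two chromosomes."""
    n_samples = len(pops)
    ploidy = np.full(n_samples, 1 if haploid else 2)
    calls = rng.integers(0, (2 if haploid else 3), (n_sites, n_samples))
    calls[rng.random((n_sites, n_samples)) < missing_rate] = -1
    half = n_sites // 2
    chrom = ["1"] * half + ["2"] * (n_sites - half)
    pos = np.concatenate(
        [
            np.cumsum(rng.integers(500, 200_000, half)),
            np.cumsum(rng.integers(500, 200_000, n_sites - half)),
        ]
    )
    pairs = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]  # transversions
    idx = rng.integers(0, len(pairs), n_sites)
    ref = [pairs[i][0] for i in idx]
    alt = [pairs[i][1] for i in idx]
    return build_matrix(calls, list(pops), ploidy, chrom, pos, ref, alt)
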