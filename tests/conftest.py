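"""Shared fixtures: small hand-constructed panels and a desk-scale
simulated dataset reused across test modules."""

import numpy as np
import pytest

from selfmix.synthetic_data import SimConfig, simulate_dataset
from selfmix.variant_io import GenotypePanel


def make_panel(chrom, pos, calls, samples=None, alleles=None, depth=None,
               degeneracy=None, het=None):
    calls = np.asarray(calls, dtype=np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(calls.shape[1])]
    return GenotypePanel(
        samples=samples,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        calls=calls,
        alleles=alleles,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        degeneracy=degeneracy,
        het=het,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One desk-scale mosaic dataset shared by HMM/block/pipeline tests."""
    cfg = SimConfig(genome_bp=4_000_000, n_chromosomes=2,
                    map_length_morgans=14.7 * 4_000_000 / 2.6e8,
                    sites_per_kb=600, seed=11)
    return simulate_dataset(cfg)
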