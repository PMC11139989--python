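import numpy as np
import pandas as pd
import pytest

from perd import synthetic_data as synth
from perd.genomic_io import GenomicInterval


@pytest.fixture(scope="session")
def small_network():
    """30 enhancers with disjoint 3-gene target sets and shared TFs."""
    net, sites = synth.generate_network(
        n_enhancers=30, n_genes=120, n_tfs=15, genome_length=3_000_000, seed=7
    )
    return net, sites


@pytest.fixture(scope="session")
def training_data(small_network):
    net, _ = small_network
    expr, openness, cell_types, truth = synth.generate_paired_training(
        net, n_cells=60, n_cell_types=6, noise_sd=0.1, seed=11
    )
    return net, expr, openness, cell_types, truth


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def brute_force_pairs(queries, subjects):
    """Quadratic all-pairs overlap oracle (half-open semantics, by hand)."""
    pairs = []
    for i, q in enumerate(queries):
        for j, s in enumerate(subjects):
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                pairs.append((i, j))
    return pairs
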