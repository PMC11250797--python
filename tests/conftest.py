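"""Shared fixtures: a small simulated study reused across test modules."""
import numpy as np
import pytest

import prc2ageindex as pai


@pytest.fixture(scope="session")
def small_layout():
    return pai.make_layout(
        chrom_len=2_000_000, n_lmrs=10, target_fraction=0.3, seed=11
    )


@pytest.fixture(scope="session")
def small_methylome(small_layout):
    return pai.simulate_methylome(small_layout, age=20, seed=21)


@pytest.fixture(scope="session")
def small_tracks(small_layout):
    return pai.simulate_chip_tracks(small_layout, n_factors=2, seed=31)


@pytest.fixture(scope="session")
def small_segmentation(small_methylome):
    return pai.call_lmrs(small_methylome)


@pytest.fixture(scope="session")
def small_hp(small_layout, small_segmentation, small_tracks):
    scored = pai.aggregate_binding(small_segmentation.regions, small_tracks)
    return pai.select_top_k(
        scored, pai.SelectionConfig(k=small_layout.n_targets)
    )


def make_count_methylome(chrom, pos, true_beta, coverage, rng, sample_id="t"):
    """Binomial count methylome around given true betas (no overdispersion)."""
    pos = np.asarray(pos, dtype=np.int64)
    n = np.full(pos.shape[0], coverage, dtype=np.int64)
    k = rng.binomial(n, np.broadcast_to(true_beta, pos.shape))
    sites = pai.make_sites(chrom, pos, ".", meth_count=k, total_count=n)
    return pai.Methylome(sample_id, sites)
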