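import pytest

from gapmend import simulate


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimConfig:
    """A compact two-chromosome study setting used across module tests."""
    return simulate.SimConfig(
        seed=11,
        n_chroms=2,
        chrom_len=120_000,
        telomere_copies=100,
        centromere_monomer_len=171,
        centromere_array_len=15_000,
        n_gaps_per_chrom=2,
        gap_len_range=(100, 500),
        donor_frag_len_range=(30_000, 60_000),
        gap_margin=3_000,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_scaffold(small_truth):
    return simulate.degrade_to_scaffold(small_truth)


@pytest.fixture(scope="session")
def small_donor(small_truth, small_scaffold):
    _, gap_truth = small_scaffold
    return simulate.make_donor(small_truth, gap_truth=gap_truth)
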