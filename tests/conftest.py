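import pytest

from lncannot import synthetic_data as synth


@pytest.fixture(scope="session")
def study():
    """Default synthetic study shared by read-only tests."""
    return synth.generate_study(synth.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """Small single-chromosome study for brute-force oracle comparisons."""
    cfg = synth.SynthConfig(
        seed=13, n_chroms=1, chrom_len=200_000, genes_per_chrom=6, n_ncrnas=60
    )
    return synth.generate_study(cfg)


@pytest.fixture
def toy_genes():
    """Two genes on one chromosome for hand-checkable classification."""
    from lncannot.genome_io import GeneModel

    return [
        GeneModel("gA", "GA", "chr1", "+", (1000, 2000),
                  [(1000, 1200), (1800, 2000)], utr5=[(1000, 1050)], utr3=[(1950, 2000)]),
        GeneModel("gB", "GB", "chr1", "+", (5000, 6000), [(5000, 6000)]),
    ]
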