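import pytest

from plasq import KmerIndex, TrainingConfig, make_benchmark_refs, train_length_binned


@pytest.fixture(scope="session")
def kmer_index() -> KmerIndex:
    return KmerIndex(3, 7)


@pytest.fixture(scope="session")
def small_refs():
    """Well-separated synthetic reference sets, small enough for fast training."""
    plasmids, chroms = make_benchmark_refs(
        n_plasmid=12, n_chrom=4, divergence=1.0, seed=7
    )
    return plasmids, chroms


@pytest.fixture(scope="session")
def trained_model(small_refs):
    """A length-binned model trained on the small reference sets."""
    plasmids, chroms = small_refs
    config = TrainingConfig(n_short=100, seed=7)
    return train_length_binned(plasmids, chroms, config)


@pytest.fixture(scope="session")
def null_stats():
    """Null experiment: both classes drawn from one identical source.

    With zero compositional divergence any trained decision rule sees
    identically distributed test fragments for both labels, so balanced
    accuracy can only fluctuate binomially around 0.5.
    """
    from plasq.benchmarks import null_symmetry

    return null_symmetry(seed=0)
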