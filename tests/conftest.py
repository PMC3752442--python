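import numpy as np
import pytest

import dualpath as dp


@pytest.fixture(scope="session")
def tiny_corpus() -> dp.Corpus:
    """Small corpus shared by fast unit tests: 8 morae, 20 words."""
    # bigram histograms over 10-word sets are coarse; the matching tolerance
    # is scaled up accordingly (the study-scale default stays 0.05)
    return dp.generate_corpus(n_morae=8, n_words=20, semantic_dim=20,
                              semantic_sparsity=0.2, n_probe_words=10,
                              n_nonwords=20, seed=11, bigram_tolerance=0.3)


@pytest.fixture()
def tiny_net(tiny_corpus) -> dp.NetworkState:
    arch = dp.dual_pathway_architecture(
        tiny_corpus.feature_dim, tiny_corpus.semantic_dim, n_ismg=10, n_astg=8)
    return dp.init_network(arch, 42)
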