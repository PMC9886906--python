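import numpy as np
import pytest

import triread as tr
from triread import network as net


@pytest.fixture(scope="session")
def lexicon():
    """The default study language (300 words)."""
    return tr.build_language(tr.LanguageSpec())


@pytest.fixture(scope="session")
def enc(lexicon):
    return tr.encode_lexicon(lexicon)


@pytest.fixture(scope="session")
def tiny_lexicon():
    """A 30-word language small enough for in-test training runs."""
    spec = tr.LanguageSpec(n_words=30, n_onsets=10, n_rimes=6,
                           n_homophone_pairs=1, exception_fraction=0.15,
                           seed=3)
    return tr.build_language(spec)


@pytest.fixture(scope="session")
def tiny_enc(tiny_lexicon):
    return tr.encode_lexicon(tiny_lexicon)


@pytest.fixture(scope="session")
def small_config():
    """A <=30-unit network config for gradient/decoder oracles."""
    return net.NetworkConfig(
        orth_size=3, sem_size=3, phon_size=4, context_size=2,
        hidden_sizes={"h_op": 3, "h_os1": 2, "h_os2": 3, "h_ps": 3,
                      "h_sp": 2, "attr_p": 2, "attr_s": 2})


@pytest.fixture(scope="session")
def trained_tiny(tiny_enc):
    """One fully trained tiny simulation (oral + frozen reading phase)."""
    cfg = net.default_config(tiny_enc)
    params = net.init_network(cfg, 0)
    net.train_oral(params, tiny_enc, net.OralCondition(ovs=30, ove=30_000),
                   np.random.default_rng(1), batch_size=4)
    params.freeze_oral()
    net.train_reading(params, tiny_enc, 20_000, np.random.default_rng(2),
                      batch_size=4)
    return params
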