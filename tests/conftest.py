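import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_reference_set():
    from plasmidnet.simulate import gen_reference_set

    return gen_reference_set(
        7, n_plasmids=6, n_chromosomes=3,
        plasmid_len=(5000, 12000), chromosome_len=(20000, 40000))
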