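import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, gc=0.5):
    from fosvir.community import random_sequence

    return random_sequence(rng, n, gc)
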