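import numpy as np
import pytest
from hypothesis import settings

from segscan import Alignment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_alignment(rng: np.random.Generator, n: int, L: int) -> Alignment:
    arr = rng.choice(list("ACGT"), size=(n, L))
    return Alignment(
        tuple(f"s{i}" for i in range(n)),
        tuple("".join(r) for r in arr),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
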