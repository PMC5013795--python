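import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viromimic.align_core import AA20, blosum62, compute_ka_params

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def ka(matrix):
    return compute_ka_params(matrix)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
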