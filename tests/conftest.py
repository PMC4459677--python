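import numpy as np
import pytest

from refqz.fastq_io import ReferenceSequence
from refqz.kmer_index import MappingParams, build_index
from refqz.simulate import SimulationConfig, generate_reference


# the four 454-style header lines used throughout as the canonical example
HEADER_BLOCK = [
    "@SRR001471.1 E96DJWM01D47CS length = 110",
    "@SRR001471.2 E96DJWM01CO1KR length = 297",
    "@SRR001471.3 E96DJWM01AL88Q length = 270",
    "@SRR001471.4 E96DJWM01ALL6A length = 274",
]
HEADER_LENGTHS = [110, 297, 270, 274]


@pytest.fixture(scope="session")
def params():
    return MappingParams()


@pytest.fixture(scope="session")
def small_ref():
    """10 kb random reference with a healthy density of CG seeds."""
    cfg = SimulationConfig(ref_length=10_000, seed=42)
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def small_index(small_ref, params):
    return build_index(small_ref, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=n))


@pytest.fixture(scope="session")
def tiny_ref():
    return ReferenceSequence(name="tiny", seq="ACGATCGTACGGATTACACGTT")
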