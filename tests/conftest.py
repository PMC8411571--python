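import numpy as np
import pytest

from ecrap1 import synthetic_data as sd


@pytest.fixture
def small_genome():
    """10-kb clean-background chromosome with 3 AP-1 and 1 EcRE planted."""
    spec = sd.SyntheticGenomeSpec(
        seed=11,
        lengths={"chr1": 10_000},
        planted=[
            ("chr1", 100, "AP-1", "+"),
            ("chr1", 2_500, "AP-1", "-"),
            ("chr1", 6_000, "AP-1", "+"),
            ("chr1", 8_000, "EcRE", "+"),
        ],
    )
    return sd.gen_genome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
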