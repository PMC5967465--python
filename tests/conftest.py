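import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from silicomate.consensus import ConsensusRecord
from silicomate.synthetic import (
    SyntheticGenomeSpec,
    mutate_genome,
    simulate_reference_with_repeats,
)


@pytest.fixture
def uniform_consensus():
    """10 kb consensus of random bases at uniform depth 10."""
    rng = np.random.default_rng(7)
    bases = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    return ConsensusRecord(id="c1", bases=bases, depths=np.full(10_000, 10))


@pytest.fixture
def small_truth():
    """20 kb diverged genome pair with two 500 bp repeat copies."""
    spec = SyntheticGenomeSpec(
        length=20_000, repeat_copies=2, repeat_length=500, seed=11
    )
    truth = simulate_reference_with_repeats(spec)
    return mutate_genome(truth, snp_rate=0.01, indel_rate=0.0005, indel_max=8, seed=12)
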