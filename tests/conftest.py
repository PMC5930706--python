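import pytest
from hypothesis import HealthCheck, settings

from ssaw.seq_io import DNA, SequenceCollection, SequenceRecord
from ssaw.synthetic_data import SimulationConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_seq_collection() -> SequenceCollection:
    """The two-sequence demonstration collection (S1=AACAA, S2=CCGCC)."""
    return SequenceCollection(
        [SequenceRecord("S1", "AACAA"), SequenceRecord("S2", "CCGCC")], DNA
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default simulated read dataset (8 x 65 reads of length 47, seed 0).

    Session-scoped: generation involves the constraint-satisfying centroid
    search, so it is built once and shared.
    """
    return generate_dataset(SimulationConfig(seed=0))
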