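import pytest

from bsmethyl import synthdata
from bsmethyl.core import Genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """5 kb GC-rich genome used across mapper/caller tests."""
    return synthdata.generate_genome(5_000, gc_fraction=0.70, seed=101)


@pytest.fixture(scope="session")
def tiny_genome() -> Genome:
    return synthdata.generate_genome(400, gc_fraction=0.70, seed=7)
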