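import numpy as np
import pytest

from rrsnp import (BUILTIN_ENZYMES, SimConfig, make_parent_genomes,
                   mark_discoverable)


@pytest.fixture(scope="session")
def cviri():
    return BUILTIN_ENZYMES["CviRI"]


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream regardless of
    # which other tests ran before it
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_genomes():
    """A 200 kb two-chromosome synthetic dataset shared across tests."""
    cfg = SimConfig(genome_length=200_000, seed=42)
    genomes = make_parent_genomes(cfg)
    mark_discoverable(genomes, BUILTIN_ENZYMES["CviRI"])
    return cfg, genomes
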