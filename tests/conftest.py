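import pytest

from retrocore.chemio import wash_dataset
from retrocore.corenet import build_network
from retrocore.fixtures import standard_library
from retrocore.fragmentation import EnumerationConfig

# hand-checkable two-anilide toy set: both molecules reduce to aniline
TOY_ANILIDES = [
    ("acetanilide", "CC(=O)Nc1ccccc1"),
    ("formanilide", "O=CNc1ccccc1"),
]


@pytest.fixture(scope="session")
def config():
    return EnumerationConfig()


@pytest.fixture(scope="session")
def anilide_network(config):
    from retrocore.chemio import RawRecord

    records = [RawRecord(name, smi) for name, smi in TOY_ANILIDES]
    molecules = wash_dataset(records)
    return molecules, build_network(molecules, config)


@pytest.fixture(scope="session")
def small_library(config):
    """Seeded 5-series + 4-decoy library with ground truth."""
    records, truth = standard_library(seed=11, n_series=5, decoys=4, config=config)
    return records, truth


@pytest.fixture(scope="session")
def small_network(small_library, config):
    records, truth = small_library
    molecules = wash_dataset(records)
    return molecules, build_network(molecules, config), truth
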