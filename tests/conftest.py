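import numpy as np
import pytest

from admixscan.genome import GenomeMap, MarkerGrid, default_bovine_map

AB = ("Angus", "Brahman")


@pytest.fixture(scope="session")
def bovine_map():
    return default_bovine_map()


@pytest.fixture(scope="session")
def toy_map():
    """Two short chromosomes; lambda = 0.02 and 0.01 at the default rate."""
    return GenomeMap((("1", 2_000_000), ("2", 1_000_000)))


@pytest.fixture(scope="session")
def one_chrom_map():
    return GenomeMap((("1", 1_000_000),))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_grid(toy_map):
    return MarkerGrid.uniform(toy_map, spacing_bp=10_000)
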