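import numpy as np
import pandas as pd
import pytest

from perturbmap.genome import default_marker_map
from perturbmap.sim import (
    ArchitectureConfig,
    LibraryConfig,
    simulate_architecture,
    simulate_cross,
    simulate_guide_library,
    simulate_segregant_barcodes,
)


@pytest.fixture(scope="session")
def marker_map():
    return default_marker_map()


@pytest.fixture(scope="session")
def genotypes(marker_map):
    return simulate_cross(169, marker_map, 0.12, seed=1)


@pytest.fixture(scope="session")
def guide_library(marker_map):
    guides, barcodes = simulate_guide_library(
        marker_map, LibraryConfig(n_guides=60, n_controls=12, n_polymorphic=4),
        seed=2,
    )
    return guides, barcodes


@pytest.fixture(scope="session")
def segregant_barcodes(genotypes):
    return simulate_segregant_barcodes(list(genotypes.index), seed=3)


@pytest.fixture(scope="session")
def architecture(genotypes, guide_library):
    guides, _ = guide_library
    return simulate_architecture(
        genotypes, guides, ArchitectureConfig(guides_per_hub=8), seed=4
    )
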