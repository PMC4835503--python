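import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nonself.simulate import (
    GenomeParams,
    generate_expression,
    generate_genome,
)

SMALL = GenomeParams(
    n_genes=1200, n_chrom=3, n_core=370, n_orphan=72,
    n_tf=24, n_nlr=9, n_hk=3, n_autophagy=3,
    n_sm_clusters=4, n_sm_genes=53, n_secreted=90,
)
SMALL_REGIONS = [("1", 1, 60), ("1", 200, 60), ("2", 150, 60), ("3", 100, 60)]


@pytest.fixture(scope="session")
def small_bundle():
    """A 1,200-gene genome with four implanted low-versatility regions."""
    return generate_genome(region_spec=SMALL_REGIONS, seed=7, params=SMALL)


@pytest.fixture(scope="session")
def small_expression(small_bundle):
    hotspots = {
        "VsSf": [("1", 200, 60), ("2", 150, 60)],
        "VsSm": [("1", 200, 60)],
        "VI": [("1", 200, 60), ("3", 300, 60)],
    }
    return generate_expression(small_bundle, seed=7, hotspot_spec=hotspots)


@pytest.fixture(scope="session")
def full_bundle():
    """The default study-sized genome (10,635 genes, 7 chromosomes)."""
    return generate_genome(seed=11)


@pytest.fixture(scope="session")
def full_expression(full_bundle):
    return generate_expression(full_bundle, seed=11)
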