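import numpy as np
import pandas as pd
import pytest

from ggxe import (
    generate_map,
    null_spec,
    random_gene_positions,
    simulate_ril_genotypes,
)


@pytest.fixture(scope="session")
def gmap():
    """Desk-scale scaffold: 5 chromosomes x 20 equally spaced markers, 85 cM."""
    return generate_map(5, 20, 85.0)


@pytest.fixture(scope="session")
def geno160(gmap):
    return simulate_ril_genotypes(gmap, 160, seed=7)


@pytest.fixture(scope="session")
def annotation(gmap):
    return random_gene_positions(gmap, 500, seed=21)


@pytest.fixture(scope="session")
def single_marker_map():
    """One marker per chromosome: five near-independent tests."""
    from ggxe.types import GeneticMap

    rows = [
        {"marker": f"m{c}", "chromosome": c, "cm": 0.0, "bp": 0} for c in range(1, 6)
    ]
    return GeneticMap(pd.DataFrame(rows))
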