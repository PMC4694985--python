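import numpy as np
import pytest

from paslink.pathway_db import GeneRole, PathwayDefinition
from paslink.synthetic import SyntheticScenario, gen_pathway_db


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_db():
    return [
        PathwayDefinition(
            "P1", "signaling",
            [GeneRole("GENE_A", 1.0), GeneRole("GENE_B", -0.5)],
        ),
        PathwayDefinition(
            "P2", "metabolic",
            [GeneRole("GENE_C", 0.5), GeneRole("GENE_D", -1.0), GeneRole("GENE_E", 0.0)],
        ),
    ]


@pytest.fixture
def random_db():
    return gen_pathway_db(SyntheticScenario(seed=7, n_pathways=50))


@pytest.fixture
def small_scenario():
    # trimmed sizes for fast unit tests; study-shaped defaults are
    # exercised by the acceptance suite
    return SyntheticScenario(
        seed=11,
        n_pathways=10,
        n_background_genes=50,
        n_cell_lines=8,
        control_layout=((3, (4, 6)), (2, (3, 5))),
    )
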