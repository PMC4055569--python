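import numpy as np
import pytest

from litgrn.expression import ExpressionDataset
from litgrn.ga import GAConfig
from litgrn.predications import Predication, SymbolMap
from litgrn.synthetic import (SyntheticSpec, generate_network,
                              simulate_expression)


@pytest.fixture
def symbol_map():
    return SymbolMap({
        "p53": "TP53", "tp53": "TP53", "bax": "BAX", "bik": "BIK",
        "mdm2": "MDM2", "cdkn1a": "CDKN1A", "atm": "ATM",
    })


@pytest.fixture
def simple_predications():
    """Three predications for TP53 biology, one per predicate."""
    return [
        Predication(pmid="1", subject_name="p53", predicate="STIMULATES",
                    object_name="Bax", subject_distance=1, object_distance=1),
        Predication(pmid="2", subject_name="MDM2", predicate="INHIBITS",
                    object_name="p53", subject_distance=1, object_distance=1),
        Predication(pmid="3", subject_name="p53", predicate="INTERACTS_WITH",
                    object_name="ATM", subject_distance=1, object_distance=1),
    ]


@pytest.fixture
def noise_free_study():
    """Small planted network and exactly-linear expression data."""
    spec = SyntheticSpec(n_genes=5, edge_density=0.4, T=8, R=3,
                         noise_sd=0.0, missing_arrays=[],
                         spurious_predication_rate=0.0,
                         shared_initial_state=False, rng_seed=7)
    topology, truth = generate_network(spec)
    ds, n_clipped = simulate_expression(truth, spec)
    assert n_clipped == 0
    return spec, topology, truth, ds


@pytest.fixture
def small_ga_config():
    """GA configuration scaled to few-regulator problems.

    The per-locus mutation rate is raised so a child sees ~0.5 expected
    mutations on a 5-gene chromosome, matching the role the full-scale rate
    plays on ~78-gene chromosomes.
    """
    return GAConfig(population_size=300, generations=120,
                    mutation_rate=0.1, rng_seed=11)


@pytest.fixture
def masked_dataset():
    """T=4, R=2 dataset with one missing array at (replicate 0, time 2)."""
    rng = np.random.default_rng(5)
    values = rng.uniform(-1, 1, size=(3, 2, 4))
    present = np.ones((2, 4), dtype=bool)
    present[0, 2] = False
    values[:, 0, 2] = np.nan
    return ExpressionDataset(genes=["A", "B", "C"], values=values,
                             present=present)
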