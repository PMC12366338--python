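import numpy as np
import pytest

from genspec import (
    OtuTable,
    SyntheticScenario,
    simulate_phylogeny,
    simulate_structured_table,
)


@pytest.fixture(scope="session")
def mini_scenario():
    """24-sample, 200-OTU scenario used across the suite."""
    return SyntheticScenario(
        n_samples=24,
        grid_shape=(6, 4),
        n_otus=200,
        n_generalists=20,
        n_specialists=60,
        community_size=2000,
        seed=5,
    )


@pytest.fixture(scope="session")
def mini_community(mini_scenario):
    table, truth, meta = simulate_structured_table(mini_scenario)
    return table.drop_empty_otus(), truth, meta


@pytest.fixture(scope="session")
def mini_tree(mini_community):
    table, _, _ = mini_community
    tree, optima = simulate_phylogeny(table.n_otus, 0.5, seed=7, otu_ids=table.otu_ids)
    return tree


@pytest.fixture()
def toy_table():
    return OtuTable(np.array([[5, 0], [0, 5]]), ["A", "B"], ["x", "y"])
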