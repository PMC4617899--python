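import numpy as np
import pytest

import bubblegum as bg
from bubblegum import simulate as sim


@pytest.fixture(scope="session")
def planted():
    """Default planted fixture: 7 classes x 3 replicates, 2000 genes, six
    50-gene blocks at a four-fold (2.0 log2) effect, plus its gene sets."""
    dataset, truth = sim.simulate_dataset(sim.default_spec(seed=1))
    collection = sim.simulate_gene_sets(truth, 12, (15, 50), seed=2,
                                        gene_universe=dataset.identifiers)
    return dataset, truth, collection


@pytest.fixture(scope="session")
def two_class_planted():
    spec = sim.SimulationSpec(n_genes=300, classes={"A": 3, "B": 3},
                              planted_blocks={"A": (20, 1.5)}, seed=3)
    return sim.simulate_dataset(spec)


@pytest.fixture
def toy_ranked():
    return bg.RankedList(genes=["g1", "g2", "g3", "g4", "g5"],
                         metrics=np.array([3.0, 2.0, 1.0, -1.0, -2.0]),
                         class_left="L", class_right="R")


def small_dataset(values, classes):
    """Build a tiny dataset from a dict sample -> class and a value matrix."""
    samples = list(classes)
    return bg.ExpressionDataset(
        identifiers=[f"g{i + 1}" for i in range(values.shape[0])],
        values=values,
        sample_names=samples,
        class_of=dict(classes),
    )
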