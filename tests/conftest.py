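import numpy as np
import pytest

from mdgcn import (
    DiseaseOntology,
    PipelineConfig,
    SyntheticSpec,
    generate_dataset,
)
from mdgcn.autoencoder import AutoencoderSpec
from mdgcn.gcn import GCNSpec


@pytest.fixture
def chain_ontology():
    """d -> p -> r."""
    return DiseaseOntology([("d", "p"), ("p", "r")])


@pytest.fixture
def diamond_ontology():
    """d with parents p1, p2, both children of root r."""
    return DiseaseOntology([("d", "p1"), ("d", "p2"), ("p1", "r"), ("p2", "r")])


@pytest.fixture(scope="session")
def tiny_spec():
    """Fast end-to-end spec: 40 x 30, rank 3, denser so folds stay balanced."""
    return SyntheticSpec(
        n_m=40, n_d=30, latent_rank=3, density=0.08,
        ontology_depth=4, branching=3, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_config():
    return PipelineConfig(
        ae=AutoencoderSpec(code_dim=16, hidden_dims=(48,), epochs=80,
                           learning_rate=3e-3, seed=7),
        gcn=GCNSpec(layer_dims=(16, 12, 8), epochs=120, seed=7),
    )


@pytest.fixture(scope="session")
def demo_data():
    """The planted-signal study dataset: 200 x 150, rank 5, density 0.03."""
    return generate_dataset(SyntheticSpec.demo(seed=1))


@pytest.fixture(scope="session")
def demo_config():
    return PipelineConfig.small(seed=1)


def random_dag_edges(rng, n_nodes, edge_prob=0.5):
    """Random DAG over str(0..n-1); child i -> parent j only for j < i."""
    edges = []
    for i in range(1, n_nodes):
        parents = [j for j in range(i) if rng.random() < edge_prob]
        if not parents:
            parents = [int(rng.integers(i))]
        edges.extend((str(i), str(j)) for j in parents)
    return edges
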