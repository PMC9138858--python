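import numpy as np
import pytest

from smmda.core_data import AssociationList, build_adjacency
from smmda.similarity import DiseaseDAG, SemanticConfig


@pytest.fixture
def toy_assocs() -> AssociationList:
    return AssociationList.from_pairs(
        [("m1", "d1"), ("m2", "d2"), ("m1", "d2"), ("m3", "d1")]
    )


@pytest.fixture
def toy_matrix(toy_assocs):
    return build_adjacency(toy_assocs)


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    # A -> B -> C: C is the grandparent of the disease A
    return DiseaseDAG(
        disease="a",
        nodes=frozenset({"a", "b", "c"}),
        edges=frozenset({("a", "b"), ("b", "c")}),
    )


@pytest.fixture
def half_delta() -> SemanticConfig:
    return SemanticConfig(delta=0.5)


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseDAG:
    """Random ancestor DAG: every node is reachable from the disease by
    construction (each new node becomes a parent of existing nodes)."""
    names = [f"n{k}" for k in range(n_nodes)]
    disease = names[0]
    edges = set()
    for k in range(1, n_nodes):
        n_children = 1 + rng.integers(0, min(2, k))
        children = rng.choice(k, size=n_children, replace=False)
        for c in children:
            edges.add((names[c], names[k]))
    return DiseaseDAG(disease=disease, nodes=frozenset(names),
                      edges=frozenset(edges))


def semantic_oracle(dag: DiseaseDAG, delta: float) -> tuple[dict, float]:
    """Path-enumeration oracle: DD(d) = max over upward root-paths from
    the disease of delta^(steps to reach d); DV = sum of contributions."""
    best: dict[str, float] = {}

    def walk(node: str, value: float) -> None:
        if value > best.get(node, 0.0):
            best[node] = value
            for parent in dag.parents(node):
                walk(parent, value * delta)

    walk(dag.disease, 1.0)
    return best, sum(best.values())
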