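import networkx as nx
import numpy as np
import pytest

from blnimda.data_io import AssociationMatrix, DagCorpus, EntityIndex, SimilarityMatrix
from blnimda.profile_kernels import SimilarityInputs
from blnimda.synthetic import SyntheticSpec, generate, worked_example


@pytest.fixture
def toy_corpus():
    """Two diseases X and Y sharing a single root ancestor R."""
    dag_x = nx.DiGraph([("r", "x")])
    dag_y = nx.DiGraph([("r", "y")])
    return DagCorpus(dags={"x": dag_x, "y": dag_y})


@pytest.fixture
def example():
    return worked_example()


@pytest.fixture
def small_identity_assoc():
    index = EntityIndex(("m1", "m2"), ("d1", "d2"))
    return AssociationMatrix(np.eye(2, dtype=int), index)


def make_inputs(data) -> SimilarityInputs:
    return SimilarityInputs.from_corpus(
        data.corpus,
        data.associations.index,
        mirna_functional=data.mirna_similarity,
        mirna_availability=data.mirna_availability,
    )


@pytest.fixture
def planted_data():
    return generate(SyntheticSpec(seed=7))


@pytest.fixture
def planted_inputs(planted_data):
    return make_inputs(planted_data)
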