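import warnings

import numpy as np
import pytest

from hlagcn.gcn_model import AffinityModel, GCNConfig
from hlagcn.hla_graph import build_residue_graph
from hlagcn.peptide_graph import build_peptide_graph
from hlagcn.synthetic_fixtures import fixture_hla_structure


@pytest.fixture(scope="session")
def helix_structure():
    return fixture_hla_structure(n_res=30, seed=1)


@pytest.fixture(scope="session")
def helix_graph(helix_structure):
    return build_residue_graph(helix_structure)


@pytest.fixture(scope="session")
def nonamer_graph():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_peptide_graph("ASAYKWLQV")


@pytest.fixture
def tiny_config():
    """Small architecture for fast structural tests (not the study config)."""
    return GCNConfig(
        hla_layer_dims=(8,),
        pep_layer_dims=(8,),
        mlp_dims=(8, 4, 1),
        n_epochs=3,
        seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return AffinityModel.initialize(tiny_config)


def zero_model(config: GCNConfig) -> AffinityModel:
    model = AffinityModel.initialize(config)
    for k in model.weights:
        model.weights[k] = np.zeros_like(model.weights[k])
    return model
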