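import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import zero_model
from hlagcn.errors import ContractError
from hlagcn.gcn_model import (
    AffinityRecord,
    BINDER_SCORE_CUTOFF,
    GCNConfig,
    classify_binder,
    gcn_layer,
    ic50_to_score,
    load_model,
    normalize_adjacency,
    predict,
    read_training_table,
    readout,
    save_model,
    score_to_ic50,
    train,
)
from hlagcn.planted import fixture_dataset
from hlagcn.synthetic_fixtures import write_training_table


class Edge:
    def __init__(self, i, j, distance=1.0):
        self.i, self.j, self.distance = i, j, distance


# ---------------------------------------------------------------- transform

@pytest.mark.parametrize(
    "ic50,expected",
    [(1.0, 1.0), (50000.0, 0.0), (500.0, 0.42562), (1e9, 0.0), (1e-6, 1.0)],
)
def test_log50k_transform(ic50, expected):
    assert ic50_to_score(ic50) == pytest.approx(expected, abs=1e-4)


def test_transform_rejects_nonpositive():
    with pytest.raises(ContractError):
        ic50_to_score(0.0)
    with pytest.raises(ContractError):
        ic50_to_score(-5.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_transform_roundtrip(score):
    back = ic50_to_score(score_to_ic50(score))
    assert abs(back - score) <= 1e-9 * max(1.0, abs(score))


def test_binder_cutoff_strict():
    assert classify_binder(0.5) == "binder"
    assert classify_binder(0.3) == "nonbinder"
    # exactly 500 nM transforms onto the cutoff: strict inequality -> nonbinder
    assert classify_binder(ic50_to_score(500.0)) == "nonbinder"
    assert BINDER_SCORE_CUTOFF == pytest.approx(1 - math.log(500) / math.log(50000))


# -------------------------------------------------------- adjacency / layer

def test_isolated_node_adjacency():
    assert np.array_equal(normalize_adjacency([], 1), [[1.0]])


def test_two_node_adjacency_hand_case():
    A = normalize_adjacency([Edge(0, 1)], 2)
    assert np.allclose(A, [[0.5, 0.5], [0.5, 0.5]])


def test_adjacency_symmetric_rowsums_not_one():
    rng = np.random.default_rng(0)
    edges = [Edge(i, j) for i, j in {(0, 1), (1, 2), (0, 3), (3, 4)}]
    A = normalize_adjacency(edges, 5)
    assert np.allclose(A, A.T)
    assert not np.allclose(A.sum(axis=1), 1.0)


def test_distance_inverse_weighting():
    A = normalize_adjacency([Edge(0, 1, distance=2.0)], 2, "distance_inverse")
    # off-diagonal weight 0.5 before augmentation: degrees 1.5 each
    assert A[0, 1] == pytest.approx(0.5 / 1.5)


def test_gcn_layer_identity_and_zero():
    x = np.array([[1.0, 2.0]])
    assert np.array_equal(gcn_layer(x, np.eye(1), np.eye(2)), x)
    assert np.array_equal(gcn_layer(x, np.eye(1), np.zeros((2, 2))), np.zeros((1, 2)))


def test_gcn_layer_shape_mismatch():
    with pytest.raises(ContractError):
        gcn_layer(np.ones((3, 4)), np.eye(3), np.ones((5, 2)))


# ------------------------------------------------------------------ readout

def test_readout_modes():
    row = np.array([[1.0, -2.0, 3.0]])
    for mode in ("mean", "sum", "max"):
        assert np.array_equal(readout(row, mode), row[0])
    two = np.vstack([row, row])
    assert np.array_equal(readout(two, "mean"), row[0])
    rng = np.random.default_rng(3)
    H = rng.normal(size=(7, 4))
    perm = rng.permutation(7)
    for mode in ("mean", "sum", "max"):
        assert np.allclose(readout(H, mode), readout(H[perm], mode))
    with pytest.raises(ContractError):
        readout(H, "median")


# ------------------------------------------------------------------ predict

def test_zero_weight_model_outputs_final_bias(tiny_config, helix_graph, nonamer_graph):
    model = zero_model(tiny_config)
    model.weights["mlp_b2"] = np.array([0.37])
    assert predict(model, helix_graph, nonamer_graph) == pytest.approx(0.37)


def test_predict_deterministic(tiny_model, helix_graph, nonamer_graph):
    a = predict(tiny_model, helix_graph, nonamer_graph)
    b = predict(tiny_model, helix_graph, nonamer_graph)
    assert a == b
    assert 0.0 <= a <= 1.0


def test_predict_invariant_to_node_relabeling(tiny_model, helix_graph, nonamer_graph):
    import copy

    from hlagcn.hla_graph import TypedEdge

    rng = np.random.default_rng(5)
    perm = rng.permutation(helix_graph.n_nodes)
    inv = np.argsort(perm)
    permuted = copy.deepcopy(helix_graph)
    permuted.node_ids = [helix_graph.node_ids[i] for i in perm]
    permuted.X = helix_graph.X[perm]
    permuted.edges = [
        TypedEdge(int(inv[e.i]), int(inv[e.j]), e.bond_type, e.distance)
        for e in helix_graph.edges
    ]
    a = predict(tiny_model, helix_graph, nonamer_graph)
    b = predict(tiny_model, permuted, nonamer_graph)
    assert a == pytest.approx(b, abs=1e-12)


def test_predict_feature_width_mismatch(tiny_model, helix_graph, nonamer_graph):
    with pytest.raises(ContractError):
        predict(tiny_model, nonamer_graph, nonamer_graph)


# ------------------------------------------------------------------- train

def test_train_rejects_empty_and_bad_targets(tiny_config, helix_graph, nonamer_graph):
    with pytest.raises(ContractError):
        train([], tiny_config)
    with pytest.raises(ContractError):
        train([(helix_graph, nonamer_graph, 1.5)], tiny_config)


def test_training_learns_constant_target(tiny_config, helix_graph, nonamer_graph):
    cfg = GCNConfig(**{**tiny_config.__dict__, "n_epochs": 15})
    data = [(helix_graph, nonamer_graph, 0.8)] * 8
    model = train(data, cfg)
    assert model.training_history[-1] < model.training_history[0]


def test_identical_seeds_identical_history(tiny_config, helix_graph, nonamer_graph):
    data = [(helix_graph, nonamer_graph, 0.4), (helix_graph, nonamer_graph, 0.7)] * 4
    h1 = train(data, tiny_config).training_history
    h2 = train(data, tiny_config).training_history
    assert h1 == h2


def test_planted_fixture_mse_halves_by_epoch_50():
    data = fixture_dataset(seed=0)
    cfg = GCNConfig(n_epochs=50, seed=0)
    model = train(data.train_set, cfg)
    assert model.training_history[49] < 0.5 * model.training_history[0]


# ------------------------------------------------------------- persistence

def test_checkpoint_roundtrip(tmp_path, tiny_config, helix_graph, nonamer_graph):
    data = [(helix_graph, nonamer_graph, 0.6)] * 4
    model = train(data, tiny_config)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.config == model.config
    assert loaded.training_history == model.training_history
    assert predict(loaded, helix_graph, nonamer_graph) == pytest.approx(
        predict(model, helix_graph, nonamer_graph)
    )


def test_affinity_record_exactly_one_representation():
    AffinityRecord("h", "ASA", ic50_nM=100.0)
    AffinityRecord("h", "ASA", transformed_score=0.5)
    with pytest.raises(ContractError):
        AffinityRecord("h", "ASA")
    with pytest.raises(ContractError):
        AffinityRecord("h", "ASA", ic50_nM=100.0, transformed_score=0.5)
    with pytest.raises(ContractError):
        AffinityRecord("h", "ASA", ic50_nM=-2.0)


def test_training_table_roundtrip(tmp_path):
    records = [
        AffinityRecord("H1", "ASAYKWLQV", ic50_nM=123.4),
        AffinityRecord("H1", "GGGGGGGGG", ic50_nM=4500.0),
    ]
    path = tmp_path / "train.tsv"
    write_training_table(records, path, structure_path="h1.pdb")
    back = read_training_table(path)
    assert [r.peptide_seq for r in back] == ["ASAYKWLQV", "GGGGGGGGG"]
    assert back[0].ic50_nM == pytest.approx(123.4)
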