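import copy
import warnings

import numpy as np
import pytest

from conftest import zero_model
from hlagcn import gradwam
from hlagcn.errors import AnnotationKeyError, ContractError
from hlagcn.gcn_model import AffinityModel, GCNConfig, train
from hlagcn.hla_graph import TypedEdge, build_residue_graph
from hlagcn.peptide_graph import build_peptide_graph, smiles_to_graph
from hlagcn.structure_io import assign_secondary_structure, read_structure, write_pdb
from hlagcn.synthetic_fixtures import gen_helix_structure


@pytest.fixture(scope="module")
def toy():
    """5-node residue graph + small peptide graph + a briefly trained model."""
    structure = assign_secondary_structure(gen_helix_structure(5, seed=3))
    hla = build_residue_graph(structure)
    pep = smiles_to_graph("NCC(=O)O")  # 5-atom toy
    cfg = GCNConfig(
        hla_layer_dims=(6,), pep_layer_dims=(6,), mlp_dims=(6, 4, 1),
        n_epochs=10, seed=11,
    )
    model = train([(hla, pep, 0.6), (hla, pep, 0.6)], cfg)
    return structure, hla, pep, model


def test_grad1_matches_finite_differences(toy):
    _, hla, pep, model = toy
    for branch in ("hla", "pep"):
        fm = gradwam.capture_feature_map(model, hla, pep, branch)
        h = 1e-5
        for i in range(fm.T.shape[0]):
            for c in range(fm.T.shape[1]):
                Tp, Tm = fm.T.copy(), fm.T.copy()
                Tp[i, c] += h
                Tm[i, c] -= h
                fd = (
                    gradwam.head_value(model, Tp, fm.other_pooled, branch)
                    - gradwam.head_value(model, Tm, fm.other_pooled, branch)
                ) / (2 * h)
                assert fm.grad1[i, c] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_second_partials_vanish_for_relu_head(toy):
    _, hla, pep, model = toy
    fm = gradwam.capture_feature_map(model, hla, pep, "pep")
    assert np.all(fm.grad2 == 0.0)
    alpha = gradwam.alpha_coefficients(fm)
    assert np.all(alpha == 1.0)


def test_alpha_hand_case():
    fm = gradwam.FeatureMap(
        T=np.array([[3.0]]), grad1=np.array([[2.0]]), grad2=np.array([[1.0]]),
        branch="pep", other_pooled=np.zeros(1), node_ids=[0],
    )
    assert gradwam.alpha_coefficients(fm)[0, 0] == pytest.approx(2.0 / 5.0)


def test_alpha_degenerate_entries_guarded():
    fm = gradwam.FeatureMap(
        T=np.array([[3.0, 0.0]]), grad1=np.array([[0.0, 0.0]]),
        grad2=np.array([[0.0, 5.0]]), branch="pep",
        other_pooled=np.zeros(1), node_ids=[0],
    )
    assert np.all(gradwam.alpha_coefficients(fm) == 1.0)


def test_capture_is_deterministic(toy):
    _, hla, pep, model = toy
    a = gradwam.capture_feature_map(model, hla, pep, "hla")
    b = gradwam.capture_feature_map(model, hla, pep, "hla")
    assert np.array_equal(a.T, b.T) and np.array_equal(a.grad1, b.grad1)


def test_unknown_branch_rejected(toy):
    _, hla, pep, model = toy
    with pytest.raises(ContractError):
        gradwam.capture_feature_map(model, hla, pep, "mlp")


def test_zero_weight_model_all_scores_zero(toy, tiny_config):
    _, hla, pep, _ = toy
    model = zero_model(tiny_config)
    with pytest.warns(UserWarning, match="all node scores equal"):
        attr = gradwam.gradwam_scores(model, hla, pep, "hla")
    assert np.all(attr.raw == 0.0) and np.all(attr.normalized == 0.0)
    assert np.all(gradwam.occlusion_scores(model, hla, pep, "hla") == 0.0)


def test_single_node_graph_degenerate_normalization(toy):
    _, hla, pep, model = toy
    single_graph = smiles_to_graph("O")  # one heavy atom
    with pytest.warns(UserWarning):
        attr = gradwam.gradwam_scores(model, hla, single_graph, "pep")
    assert attr.normalized.tolist() == [0.0]


def test_scores_permutation_equivariant(toy):
    _, hla, pep, model = toy
    base = gradwam.gradwam_scores(model, hla, pep, "hla")
    rng = np.random.default_rng(2)
    perm = rng.permutation(hla.n_nodes)
    inv = np.argsort(perm)
    permuted = copy.deepcopy(hla)
    permuted.node_ids = [hla.node_ids[i] for i in perm]
    permuted.X = hla.X[perm]
    permuted.edges = [
        TypedEdge(int(inv[e.i]), int(inv[e.j]), e.bond_type, e.distance)
        for e in hla.edges
    ]
    permuted_attr = gradwam.gradwam_scores(model, permuted, pep, "hla")
    assert np.allclose(permuted_attr.raw, base.raw[perm], atol=1e-10)
    assert permuted_attr.omega == pytest.approx(base.omega)


def test_normalization_bounds(toy):
    _, hla, pep, model = toy
    attr = gradwam.gradwam_scores(model, hla, pep, "hla")
    if attr.raw.max() > attr.raw.min():
        assert attr.normalized.min() == 0.0 and attr.normalized.max() == 1.0


def test_annotate_structure_roundtrip(toy, tmp_path):
    structure, hla, pep, model = toy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attr = gradwam.gradwam_scores(model, hla, pep, "hla")
    out = tmp_path / "colored.pdb"
    gradwam.annotate_structure(structure, attr, out)
    assert len(read_structure(out).residues) == len(attr.node_ids)
    # B-factor column carries 100 x normalized score at 2-decimal precision
    by_residue = {}
    for line in out.read_text().splitlines():
        if line.startswith("ATOM"):
            by_residue[int(line[22:26])] = float(line[60:66])
    expected = {rid[1]: 100.0 * v for rid, v in zip(attr.node_ids, attr.normalized)}
    for resnum, b in by_residue.items():
        assert b == pytest.approx(expected[resnum], abs=0.005)
    if attr.raw.max() > attr.raw.min():
        assert max(by_residue.values()) == pytest.approx(100.0)


def test_annotate_unknown_residue_raises(toy, tmp_path):
    structure, hla, pep, model = toy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attr = gradwam.gradwam_scores(model, hla, pep, "hla")
    attr.node_ids[0] = ("Z", 99)
    with pytest.raises(AnnotationKeyError):
        gradwam.annotate_structure(structure, attr, tmp_path / "x.pdb")


def test_occlusion_symmetry_for_duplicate_isolated_nodes(tiny_config):
    """Two isolated identical nodes must get identical occlusion deltas."""
    import hlagcn.hla_graph as hg

    X = np.zeros((2, 43))
    X[:, 0] = 1.0
    graph = hg.ResidueGraph(node_ids=[("A", 1), ("A", 2)], X=X, edges=[])
    pep = smiles_to_graph("NCC(=O)O")
    model = AffinityModel.initialize(tiny_config)
    deltas = gradwam.occlusion_scores(model, graph, pep, "hla")
    assert deltas[0] == pytest.approx(deltas[1])
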