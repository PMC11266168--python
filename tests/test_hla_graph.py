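import copy

import numpy as np
import pytest

from hlagcn.errors import EmptyStructureError, FeaturizationError
from hlagcn.hla_graph import (
    DISULFIDE,
    FEATURE_WIDTH,
    HYDROGEN,
    IONIC,
    PEPTIDE,
    ResidueGraph,
    TypedEdge,
    build_residue_graph,
    detect_hbond,
    detect_ionic,
    detect_peptide_bonds,
    encode_residue,
)
from hlagcn.structure_io import Atom, ProteinStructure, Residue
from hlagcn.synthetic_fixtures import gen_helix_structure
from hlagcn.structure_io import assign_secondary_structure

BLOCKS = {"blosum": slice(0, 21), "ss": slice(21, 29), "xyz": slice(29, 32),
          "da": slice(32, 36), "aaphy7": slice(36, 43)}


def _residue(code1, name3, ss8="H", coord=(1.0, 2.0, 3.0)):
    return Residue(
        chain_id="A", seq_index=1, name3=name3, code1=code1,
        atoms={"CA": Atom("CA", "C", np.array(coord))}, ss8=ss8,
    )


def test_encode_ala_block_layout():
    v = encode_residue(_residue("A", "ALA"))
    assert v.shape == (FEATURE_WIDTH,)
    # BLOSUM62 A-vs-A substitution score is 4, scaled by 1/10
    assert v[0] == pytest.approx(0.4)
    assert v[20] == 0.0
    ss = v[BLOCKS["ss"]]
    assert ss.sum() == 1.0 and ss[0] == 1.0  # H is the first state
    assert np.allclose(v[BLOCKS["xyz"]], [1.0, 2.0, 3.0])
    da = v[BLOCKS["da"]]
    assert da.sum() == 1.0 and da[3] == 1.0  # ALA is neither donor nor acceptor
    assert v[BLOCKS["aaphy7"]][0] == pytest.approx(1.28)  # steric parameter


@pytest.mark.parametrize(
    "code1,name3,slot",
    [("R", "ARG", 0), ("K", "LYS", 0), ("W", "TRP", 0),
     ("D", "ASP", 1), ("E", "GLU", 1),
     ("N", "ASN", 2), ("Q", "GLN", 2), ("H", "HIS", 2), ("S", "SER", 2),
     ("T", "THR", 2), ("Y", "TYR", 2),
     ("A", "ALA", 3), ("G", "GLY", 3)],
)
def test_donor_acceptor_classes(code1, name3, slot):
    v = encode_residue(_residue(code1, name3, ss8="C"))
    assert v[BLOCKS["da"]][slot] == 1.0


def test_unknown_residue_uses_dedicated_slot():
    v = encode_residue(_residue("X", "MSE"))
    assert v[20] == 1.0
    assert np.all(v[:20] == 0.0)
    assert v.shape == (FEATURE_WIDTH,)


def test_missing_ca_raises():
    r = _residue("A", "ALA")
    del r.atoms["CA"]
    with pytest.raises(FeaturizationError, match="ALA"):
        encode_residue(r)


def test_helix_has_n_minus_one_peptide_bonds(helix_structure):
    edges = detect_peptide_bonds(helix_structure)
    assert len(edges) == 29
    assert all(e.bond_type == PEPTIDE and e.j == e.i + 1 for e in edges)


def test_peptide_bonds_do_not_cross_chains():
    a = gen_helix_structure(5, seed=0, chain_id="A")
    b = gen_helix_structure(5, seed=1, chain_id="B")
    merged = ProteinStructure(id="two", chains=["A", "B"], residues=a.residues + b.residues)
    edges = detect_peptide_bonds(merged)
    assert len(edges) == 8
    assert not any(e.i < 5 <= e.j for e in edges)


def test_single_residue_has_no_peptide_bonds():
    s = ProteinStructure(id="one", chains=["A"], residues=[_residue("A", "ALA")])
    assert detect_peptide_bonds(s) == []


def test_engineered_disulfide_detected():
    seq = "ACAAAAACAA"
    s = gen_helix_structure(10, seq=seq, disulfide_pairs=((1, 7),))
    graph = build_residue_graph(assign_secondary_structure(s))
    ss_edges = [e for e in graph.edges if e.bond_type == DISULFIDE]
    assert len(ss_edges) == 1
    assert ss_edges[0].distance == pytest.approx(2.04, abs=1e-6)
    assert (ss_edges[0].i, ss_edges[0].j) == (1, 7)


def test_planted_salt_bridge_detected():
    seq = "AKAAAAAEAA"
    s = gen_helix_structure(10, seq=seq, ionic_pairs=((1, 7),))
    edges = detect_ionic(s)
    assert len(edges) == 1
    assert edges[0].bond_type == IONIC
    assert edges[0].distance == pytest.approx(3.5, abs=1e-6)


def test_hbond_excludes_peptide_bonded_neighbors():
    # two consecutive glycines with backbone N--O well inside hbond range
    r1 = Residue("A", 1, "GLY", "G", atoms={
        "N": Atom("N", "N", np.array([0.0, 1.2, 0.0])),
        "CA": Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
        "C": Atom("C", "C", np.array([1.4, 0.0, 0.0])),
        "O": Atom("O", "O", np.array([1.4, -1.2, 0.0])),
    })
    r2 = Residue("A", 2, "GLY", "G", atoms={
        "N": Atom("N", "N", np.array([2.6, 0.0, 0.0])),
        "CA": Atom("CA", "C", np.array([3.8, 0.0, 0.0])),
        "C": Atom("C", "C", np.array([5.2, 0.0, 0.0])),
        "O": Atom("O", "O", np.array([5.2, 1.2, 0.0])),
    })
    s = ProteinStructure(id="gg", chains=["A"], residues=[r1, r2])
    assert detect_peptide_bonds(s)  # precondition: they are peptide-bonded
    assert detect_hbond(s) == []


def test_hbond_between_nonbonded_residues():
    r1 = Residue("A", 1, "GLY", "G", atoms={
        "N": Atom("N", "N", np.array([0.0, 0.0, 0.0])),
        "CA": Atom("CA", "C", np.array([1.5, 0.0, 0.0])),
        "O": Atom("O", "O", np.array([2.0, 1.0, 0.0])),
    })
    r3 = Residue("A", 9, "GLY", "G", atoms={
        "N": Atom("N", "N", np.array([2.0, 4.0, 0.0])),
        "CA": Atom("CA", "C", np.array([3.0, 5.0, 0.0])),
        "O": Atom("O", "O", np.array([4.0, 6.0, 0.0])),
    })
    s = ProteinStructure(id="far", chains=["A"], residues=[r1, r3])
    edges = detect_hbond(s)
    assert len(edges) == 1
    assert edges[0].bond_type == HYDROGEN
    assert edges[0].distance == pytest.approx(3.0)  # N(1)..O is min pair distance


def test_build_residue_graph_shape_and_determinism(helix_structure):
    g1 = build_residue_graph(helix_structure)
    g2 = build_residue_graph(helix_structure)
    assert g1.X.shape == (30, FEATURE_WIDTH)
    assert g1.node_ids == [("A", i) for i in range(1, 31)]
    assert len(g1.edges) >= 29
    assert np.array_equal(g1.X, g2.X) and g1.edges == g2.edges


def test_chain_policy_single_missing_chain(helix_structure):
    with pytest.raises(EmptyStructureError):
        build_residue_graph(helix_structure, chain_policy="single:B")


def test_translation_changes_only_position_block(helix_structure):
    g = build_residue_graph(helix_structure)
    shifted = copy.deepcopy(helix_structure)
    for r in shifted.residues:
        for a in r.atoms.values():
            a.coord = a.coord + np.array([5.0, -3.0, 11.0])
    g2 = build_residue_graph(shifted)
    assert [(e.i, e.j, e.bond_type) for e in g2.edges] == [
        (e.i, e.j, e.bond_type) for e in g.edges
    ]
    assert np.allclose([e.distance for e in g2.edges], [e.distance for e in g.edges])
    assert np.allclose(g2.X[:, BLOCKS["xyz"]] - g.X[:, BLOCKS["xyz"]], [5.0, -3.0, 11.0])
    others = np.r_[0:29, 32:43]
    assert np.allclose(g2.X[:, others], g.X[:, others])


def test_edge_storage_normalized_and_symmetric():
    e = TypedEdge(5, 2, PEPTIDE, 1.3)
    assert (e.i, e.j) == (2, 5)
    with pytest.raises(FeaturizationError):
        TypedEdge(3, 3, PEPTIDE, 1.3)
    with pytest.raises(FeaturizationError):
        TypedEdge(1, 2, PEPTIDE, -1.0)


def test_json_roundtrip_lossless(helix_graph):
    text = helix_graph.to_json()
    g2 = ResidueGraph.from_json(text)
    assert g2.node_ids == helix_graph.node_ids
    assert np.array_equal(g2.X, helix_graph.X)
    assert g2.edges == helix_graph.edges
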