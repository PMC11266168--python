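"""Residue-level attributed graph of an HLA structure.

Nodes are residues with a 43-dimensional feature vector laid out in fixed
blocks: BLOSUM62 residue-type encoding (21), 8-state secondary structure
one-hot (8), C-alpha position in Angstrom (3), hydrogen donor/acceptor class
one-hot (4) and AAPHY7 physicochemical descriptors (7).  Edges are typed
chemical bonds — peptide, hydrogen, ionic, disulfide — detected from heavy-
atom geometry, each carrying the measured distance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .constants import (
    ACCEPTOR_RESIDUES,
    ACIDIC_SIDECHAIN_O,
    AAPHY7,
    AAPHY7_X,
    BASIC_SIDECHAIN_N,
    DONOR_ACCEPTOR_RESIDUES,
    DONOR_RESIDUES,
    SIDECHAIN_ACCEPTOR_ATOMS,
    SIDECHAIN_DONOR_ATOMS,
    SS8_STATES,
    STANDARD_AA,
)
from .errors import EmptyStructureError, FeaturizationError
from .structure_io import ProteinStructure, Residue

FEATURE_WIDTH = 43
BLOSUM_WIDTH = 21
SS_WIDTH = 8
POSITION_WIDTH = 3
DONOR_ACCEPTOR_WIDTH = 4
AAPHY7_WIDTH = 7

PEPTIDE = "PEPTIDE"
HYDROGEN = "HYDROGEN"
IONIC = "IONIC"
DISULFIDE = "DISULFIDE"
BOND_TYPES = (PEPTIDE, HYDROGEN, IONIC, DISULFIDE)

# Geometric detector cutoffs in Angstrom (frozen defaults, overridable).
PEPTIDE_C_N_CUTOFF = 1.8
PEPTIDE_CA_CA_CUTOFF = 4.5
DISULFIDE_SG_CUTOFF = 2.5
IONIC_CUTOFF = 4.0
HBOND_CUTOFF = 3.5

BLOSUM_SCALE = 0.1

_blosum62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ROWS = {
    a: np.array([float(_blosum62[a][b]) for b in STANDARD_AA]) for a in STANDARD_AA
}


@dataclass(frozen=True)
class TypedEdge:
    """Undirected typed bond between residues i < j with measured distance."""

    i: int
    j: int
    bond_type: str
    distance: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise FeaturizationError("self-loop edges are not stored")
        if self.distance <= 0:
            raise FeaturizationError("edge distance must be positive")
        if self.i > self.j:  # normalize orientation
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)


def _edge(i: int, j: int, bond_type: str, distance: float) -> TypedEdge:
    return TypedEdge(min(i, j), max(i, j), bond_type, float(distance))


@dataclass
class ResidueGraph:
    node_ids: list[tuple[str, int]]
    X: np.ndarray
    edges: list[TypedEdge]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.node_ids)
        if self.X.shape != (n, FEATURE_WIDTH):
            raise FeaturizationError(
                f"feature matrix shape {self.X.shape} != ({n}, {FEATURE_WIDTH})"
            )
        for e in self.edges:
            if not (0 <= e.i < n and 0 <= e.j < n):
                raise FeaturizationError(f"edge ({e.i},{e.j}) out of range for N={n}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": "residue_graph",
            "feature_width": FEATURE_WIDTH,
            "node_ids": [[c, i] for c, i in self.node_ids],
            "X": self.X.tolist(),
            "edges": [[e.i, e.j, e.bond_type, e.distance] for e in self.edges],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ResidueGraph":
        payload = json.loads(text)
        return cls(
            node_ids=[(c, int(i)) for c, i in payload["node_ids"]],
            X=np.array(payload["X"], dtype=float),
            edges=[_edge(i, j, t, d) for i, j, t, d in payload["edges"]],
        )

    @classmethod
    def from_json_file(cls, path: str | Path) -> "ResidueGraph":
        return cls.from_json(Path(path).read_text())


def donor_acceptor_class(code1: str) -> int:
    """Donor/acceptor class index: 0=donor, 1=acceptor, 2=both, 3=neither."""
    if code1 in DONOR_RESIDUES:
        return 0
    if code1 in ACCEPTOR_RESIDUES:
        return 1
    if code1 in DONOR_ACCEPTOR_RESIDUES:
        return 2
    return 3


def encode_residue(
    r: Residue,
    center: np.ndarray | None = None,
    blosum_scale: float = BLOSUM_SCALE,
) -> np.ndarray:
    """43-dim feature vector in block order (blosum, ss, position, d/a, aaphy7)."""
    if r.ca is None:
        raise FeaturizationError(
            f"residue {r.chain_id}:{r.seq_index} ({r.name3}) has no C-alpha atom"
        )
    blosum = np.zeros(BLOSUM_WIDTH)
    if r.code1 in _BLOSUM_ROWS:
        blosum[:20] = _BLOSUM_ROWS[r.code1] * blosum_scale
    else:  # unknown residue -> dedicated 21st slot
        blosum[20] = 1.0

    ss = np.zeros(SS_WIDTH)
    if r.ss8 in SS8_STATES:
        ss[SS8_STATES.index(r.ss8)] = 1.0
    else:
        raise FeaturizationError(
            f"residue {r.chain_id}:{r.seq_index} has no secondary-structure label; "
            "run assign_secondary_structure first"
        )

    xyz = r.ca.coord.astype(float)
    if center is not None:
        xyz = xyz - center

    da = np.zeros(DONOR_ACCEPTOR_WIDTH)
    da[donor_acceptor_class(r.code1)] = 1.0

    phy = np.array(AAPHY7.get(r.code1, AAPHY7_X), dtype=float)
    return np.concatenate([blosum, ss, xyz, da, phy])


def _atom_coord(r: Residue, name: str) -> np.ndarray | None:
    a = r.atoms.get(name)
    return None if a is None else a.coord


def detect_peptide_bonds(
    s: ProteinStructure,
    c_n_cutoff: float = PEPTIDE_C_N_CUTOFF,
    ca_ca_cutoff: float = PEPTIDE_CA_CA_CUTOFF,
) -> list[TypedEdge]:
    """Backbone links between residues consecutive within each chain.

    Primary criterion is the carbonyl-C to amide-N distance; when either
    backbone atom is missing the C-alpha pair distance is used instead.
    """
    index_of = {id(r): k for k, r in enumerate(s.residues)}
    edges = []
    for chain in s.chains:
        residues = s.chain_residues(chain)
        for a, b in itertools.pairwise(residues):
            c, n = _atom_coord(a, "C"), _atom_coord(b, "N")
            if c is not None and n is not None:
                d = float(np.linalg.norm(c - n))
                if d <= c_n_cutoff:
                    edges.append(_edge(index_of[id(a)], index_of[id(b)], PEPTIDE, d))
                continue
            ca1, ca2 = _atom_coord(a, "CA"), _atom_coord(b, "CA")
            if ca1 is not None and ca2 is not None:
                d = float(np.linalg.norm(ca1 - ca2))
                if d <= ca_ca_cutoff:
                    edges.append(_edge(index_of[id(a)], index_of[id(b)], PEPTIDE, d))
    return edges


def detect_disulfide(
    s: ProteinStructure, cutoff: float = DISULFIDE_SG_CUTOFF
) -> list[TypedEdge]:
    """Cystine bridges: CYS SG-SG pairs within the covalent S-S range."""
    cys = [
        (k, r.atoms["SG"].coord)
        for k, r in enumerate(s.residues)
        if r.code1 == "C" and "SG" in r.atoms
    ]
    edges = []
    for (i, ci), (j, cj) in itertools.combinations(cys, 2):
        d = float(np.linalg.norm(ci - cj))
        if d <= cutoff:
            edges.append(_edge(i, j, DISULFIDE, d))
    return edges


def detect_ionic(s: ProteinStructure, cutoff: float = IONIC_CUTOFF) -> list[TypedEdge]:
    """Salt bridges: basic side-chain N within range of acidic side-chain O."""
    basic, acidic = [], []
    for k, r in enumerate(s.residues):
        for name in BASIC_SIDECHAIN_N.get(r.name3, ()):
            if name in r.atoms:
                basic.append((k, r.atoms[name].coord))
        for name in ACIDIC_SIDECHAIN_O.get(r.name3, ()):
            if name in r.atoms:
                acidic.append((k, r.atoms[name].coord))
    best: dict[tuple[int, int], float] = {}
    for (i, ci), (j, cj) in itertools.product(basic, acidic):
        if i == j:
            continue
        d = float(np.linalg.norm(ci - cj))
        if d <= cutoff:
            key = (min(i, j), max(i, j))
            if d < best.get(key, np.inf):
                best[key] = d
    return [_edge(i, j, IONIC, d) for (i, j), d in sorted(best.items())]


def detect_hbond(s: ProteinStructure, cutoff: float = HBOND_CUTOFF) -> list[TypedEdge]:
    """Hydrogen bonds by heavy-atom donor-acceptor distance.

    Donors: backbone N of every residue plus side-chain N/O of donor-capable
    residues; acceptors: backbone O plus side-chain O (and imidazole N) of
    acceptor-capable residues.  Residue pairs already joined by a peptide
    bond are excluded; one edge (minimum distance) is kept per pair.
    """
    peptide_pairs = {(e.i, e.j) for e in detect_peptide_bonds(s)}
    donors, acceptors = [], []
    for k, r in enumerate(s.residues):
        if "N" in r.atoms:
            donors.append((k, r.atoms["N"].coord))
        if "O" in r.atoms:
            acceptors.append((k, r.atoms["O"].coord))
        for name in SIDECHAIN_DONOR_ATOMS.get(r.code1, ()):
            if name in r.atoms:
                donors.append((k, r.atoms[name].coord))
        for name in SIDECHAIN_ACCEPTOR_ATOMS.get(r.code1, ()):
            if name in r.atoms:
                acceptors.append((k, r.atoms[name].coord))
    best: dict[tuple[int, int], float] = {}
    for (i, ci), (j, cj) in itertools.product(donors, acceptors):
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in peptide_pairs:
            continue
        d = float(np.linalg.norm(ci - cj))
        if d <= cutoff and d < best.get(key, np.inf):
            best[key] = d
    return [_edge(i, j, HYDROGEN, d) for (i, j), d in sorted(best.items())]


def build_residue_graph(
    s: ProteinStructure,
    chain_policy: str = "merge_all",
    center_coords: bool = False,
    blosum_scale: float = BLOSUM_SCALE,
    cutoffs: dict[str, float] | None = None,
) -> ResidueGraph:
    """Assemble the attributed residue graph of a structure.

    ``chain_policy`` is ``"merge_all"`` (class II alpha+beta in one graph) or
    ``"single:<chain id>"``.  Edge duplicates across bond types are retained
    as separate typed edges.
    """
    cutoffs = cutoffs or {}
    if chain_policy == "merge_all":
        selected = s
    elif chain_policy.startswith("single:"):
        chain = chain_policy.split(":", 1)[1]
        residues = s.chain_residues(chain)
        if not residues:
            raise EmptyStructureError(
                f"chain policy {chain_policy!r}: no residues in chain {chain!r}"
            )
        selected = ProteinStructure(id=s.id, chains=[chain], residues=residues)
    else:
        raise EmptyStructureError(f"unknown chain policy {chain_policy!r}")

    residues = [r for r in selected.residues if r.ca is not None]
    if not residues:
        raise EmptyStructureError(f"{s.id}: no residues with C-alpha after selection")
    selected = ProteinStructure(id=selected.id, chains=selected.chains, residues=residues)

    center = None
    if center_coords:
        center = np.mean([r.ca.coord for r in residues], axis=0)
    X = np.stack([encode_residue(r, center=center, blosum_scale=blosum_scale) for r in residues])

    edges = (
        detect_peptide_bonds(
            selected,
            c_n_cutoff=cutoffs.get("peptide_c_n", PEPTIDE_C_N_CUTOFF),
            ca_ca_cutoff=cutoffs.get("peptide_ca_ca", PEPTIDE_CA_CA_CUTOFF),
        )
        + detect_hbond(selected, cutoff=cutoffs.get("hbond", HBOND_CUTOFF))
        + detect_ionic(selected, cutoff=cutoffs.get("ionic", IONIC_CUTOFF))
        + detect_disulfide(selected, cutoff=cutoffs.get("disulfide", DISULFIDE_SG_CUTOFF))
    )
    return ResidueGraph(
        node_ids=[r.key() for r in residues],
        X=X,
        edges=edges,
    )
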