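"""Peptide sequences as atom-level molecular graphs.

A peptide is assembled residue-by-residue into a linear SMILES string
(backbone N-CA-C(=O) units condensed with loss of one water per bond, free
N-terminus, carboxylate C-terminus) and parsed with RDKit into a heavy-atom
graph.  Each atom carries a 22-dimensional feature vector in fixed block
order: element one-hot over [H,C,N,O,F,Cl,S,Br,I] (9), atomic number,
acceptor flag, donor flag, aromatic flag, hybridization one-hot [sp,sp2,sp3]
(3), connected hydrogens, formal charge, explicit valence, implicit valence,
implicit-H count and radical electrons.  Aromatic rings are kekulized so
every bond has integer order single/double/triple; aromaticity survives as
an atom feature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .constants import SIDECHAIN_SMILES, STANDARD_AA
from .errors import SmilesParseError, UnsupportedResidueError

FEATURE_WIDTH = 22
ELEMENTS = ("H", "C", "N", "O", "F", "Cl", "S", "Br", "I")
HYBRIDIZATIONS = ("SP", "SP2", "SP3")
BOND_ORDERS = ("SINGLE", "DOUBLE", "TRIPLE")

# Peptide lengths the binding groove biology makes typical; outside this
# range we warn but proceed.
TYPICAL_LENGTH_RANGE = (8, 25)


def _residue_unit(code: str) -> str:
    """Backbone+side-chain SMILES unit of one residue inside a chain."""
    if code == "G":
        return "NCC(=O)"
    if code == "P":  # pyrrolidine ring closes side chain onto backbone N
        return "N1CCCC1C(=O)"
    return f"NC({SIDECHAIN_SMILES[code]})C(=O)"


# Heavy atoms contributed by each in-chain residue unit (terminal carboxyl O
# belongs to the last residue and is counted separately).
UNIT_HEAVY_ATOMS = {
    aa: Chem.MolFromSmiles(_residue_unit(aa)).GetNumAtoms() for aa in STANDARD_AA
}
# Heavy atoms of the free amino acid, for the condensation count formula
# total = sum(residue_heavy) - (L - 1).
RESIDUE_HEAVY_ATOMS = {aa: n + 1 for aa, n in UNIT_HEAVY_ATOMS.items()}


def peptide_to_smiles(seq: str) -> str:
    """Assemble the linear-peptide SMILES of a 1-letter sequence."""
    if not seq:
        raise UnsupportedResidueError("empty peptide sequence")
    bad = sorted(set(seq) - set(STANDARD_AA))
    if bad:
        raise UnsupportedResidueError(
            f"unsupported residue letter(s) {bad} in peptide {seq!r}"
        )
    lo, hi = TYPICAL_LENGTH_RANGE
    if not (lo <= len(seq) <= hi):
        warnings.warn(
            f"peptide length {len(seq)} outside the typical {lo}-{hi} groove range",
            stacklevel=2,
        )
    return "".join(_residue_unit(a) for a in seq) + "O"


@dataclass(frozen=True)
class MolecularAtom:
    element: str
    atomic_num: int
    is_acceptor: int
    is_donor: int
    is_aromatic: int
    hybridization: str
    n_hydrogens: int
    formal_charge: int
    explicit_valence: int
    implicit_valence: int
    n_implicit_h: int
    n_radical_electrons: int

    def feature_vector(self) -> np.ndarray:
        v = np.zeros(FEATURE_WIDTH)
        if self.element in ELEMENTS:
            v[ELEMENTS.index(self.element)] = 1.0
        v[9] = self.atomic_num
        v[10] = self.is_acceptor
        v[11] = self.is_donor
        v[12] = self.is_aromatic
        if self.hybridization in HYBRIDIZATIONS:
            v[13 + HYBRIDIZATIONS.index(self.hybridization)] = 1.0
        v[16] = self.n_hydrogens
        v[17] = self.formal_charge
        v[18] = self.explicit_valence
        v[19] = self.implicit_valence
        v[20] = self.n_implicit_h
        v[21] = self.n_radical_electrons
        return v


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str  # one of BOND_ORDERS

    def order_onehot(self) -> np.ndarray:
        v = np.zeros(3)
        v[BOND_ORDERS.index(self.order)] = 1.0
        return v


@dataclass
class AtomGraph:
    atoms: list[MolecularAtom]
    X: np.ndarray
    bonds: list[Bond]
    atom_to_residue: list[tuple[int, str]]  # (1-based peptide position, code)

    @property
    def n_nodes(self) -> int:
        return len(self.atoms)

    @property
    def edges(self) -> list[Bond]:  # adjacency-building alias
        return self.bonds

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": "atom_graph",
            "feature_width": FEATURE_WIDTH,
            "X": self.X.tolist(),
            "atoms": [a.__dict__ for a in self.atoms],
            "bonds": [[b.i, b.j, b.order] for b in self.bonds],
            "atom_to_residue": [[p, c] for p, c in self.atom_to_residue],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "AtomGraph":
        payload = json.loads(text)
        return cls(
            atoms=[MolecularAtom(**a) for a in payload["atoms"]],
            X=np.array(payload["X"], dtype=float),
            bonds=[Bond(i, j, o) for i, j, o in payload["bonds"]],
            atom_to_residue=[(int(p), c) for p, c in payload["atom_to_residue"]],
        )

    @classmethod
    def from_json_file(cls, path: str | Path) -> "AtomGraph":
        return cls.from_json(Path(path).read_text())


def _atom_features(atom: Chem.Atom, aromatic: bool) -> MolecularAtom:
    symbol = atom.GetSymbol()
    n_h = atom.GetTotalNumHs()
    # Simple lone-pair rules: any O accepts; N accepts unless its lone pair
    # is tied up in an amide/aromatic system with an attached H; N or O with
    # >=1 H donates.
    is_donor = int(symbol in ("N", "O") and n_h >= 1)
    is_acceptor = int(symbol == "O" or (symbol == "N" and n_h == 0))
    return MolecularAtom(
        element=symbol,
        atomic_num=atom.GetAtomicNum(),
        is_acceptor=is_acceptor,
        is_donor=is_donor,
        is_aromatic=int(aromatic),
        hybridization=str(atom.GetHybridization()),
        n_hydrogens=n_h,
        formal_charge=atom.GetFormalCharge(),
        explicit_valence=atom.GetExplicitValence(),
        implicit_valence=atom.GetImplicitValence(),
        n_implicit_h=atom.GetNumImplicitHs(),
        n_radical_electrons=atom.GetNumRadicalElectrons(),
    )


def smiles_to_graph(
    smiles: str,
    explicit_h: bool = False,
    atom_to_residue: list[tuple[int, str]] | None = None,
) -> AtomGraph:
    """Parse a SMILES string into a featurized molecular graph.

    Heavy-atom graph by default: hydrogens are counted into the per-atom
    hydrogen features rather than added as nodes (``explicit_h=True`` adds
    them).  Atom order follows the SMILES string, which the peptide
    assembler relies on for the atom-to-residue map.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if explicit_h:
        mol = Chem.AddHs(mol)
    aromatic_flags = [a.GetIsAromatic() for a in mol.GetAtoms()]
    Chem.Kekulize(mol, clearAromaticFlags=True)

    atoms = [
        _atom_features(a, aromatic_flags[a.GetIdx()]) for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = str(b.GetBondType())
        if order not in BOND_ORDERS:
            raise SmilesParseError(
                f"bond order {order} not in single/double/triple after kekulization"
            )
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(Bond(min(i, j), max(i, j), order))

    if atom_to_residue is None:
        atom_to_residue = [(1, "?")] * len(atoms)
    if len(atom_to_residue) != len(atoms):
        raise SmilesParseError(
            f"atom_to_residue length {len(atom_to_residue)} != atom count {len(atoms)}"
        )
    X = np.stack([a.feature_vector() for a in atoms]) if atoms else np.zeros((0, FEATURE_WIDTH))
    return AtomGraph(atoms=atoms, X=X, bonds=bonds, atom_to_residue=atom_to_residue)


def build_peptide_graph(seq: str) -> AtomGraph:
    """Sequence -> SMILES -> featurized heavy-atom graph with residue map."""
    smiles = peptide_to_smiles(seq)
    mapping: list[tuple[int, str]] = []
    for pos, aa in enumerate(seq, start=1):
        mapping.extend([(pos, aa)] * UNIT_HEAVY_ATOMS[aa])
    mapping.append((len(seq), seq[-1]))  # terminal carboxyl oxygen
    return smiles_to_graph(smiles, atom_to_residue=mapping)


def read_peptides(path: str | Path) -> list[str]:
    """Read peptides from FASTA or one-sequence-per-line text."""
    lines = Path(path).read_text().splitlines()
    seqs: list[str] = []
    if any(line.startswith(">") for line in lines):
        current: list[str] = []
        for line in lines:
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            elif line.strip():
                current.append(line.strip())
        if current:
            seqs.append("".join(current))
    else:
        seqs = [line.strip() for line in lines if line.strip()]
    return seqs
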