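"""Protein structure input/output and secondary-structure assignment.

Structures are read from PDB files into a lightweight residue-centric
container: each residue keeps its chain, author numbering, residue type and
a map of heavy atoms with coordinates in Angstrom.  Secondary structure uses
the 8-state DSSP alphabet {H,B,E,T,G,I,S,C}; labels are either copied from
an external annotation file or assigned by a coarse C-alpha-geometry
fallback that only ever emits H, E or C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .constants import SS8_STATES, THREE_TO_ONE
from .errors import (
    AnnotationKeyError,
    EmptyStructureError,
    StructureParseError,
)

UNKNOWN_SS = "?"

# Geometry-fallback thresholds (Angstrom), frozen after calibration on the
# ideal-helix fixture: an i->i+3 C-alpha distance inside [4.5, 6.5] over four
# consecutive offsets marks a helical window; an i->i+2 distance above 6.0
# over a 3-residue window marks a locally extended strand.
HELIX_D13_RANGE = (4.5, 6.5)
STRAND_D02_MIN = 6.0


@dataclass
class Atom:
    """A heavy atom with PDB-convention name and coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureParseError(
                f"atom {self.name!r}: coordinate must be a finite 3-vector"
            )


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    name3: str
    code1: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    ss8: str = UNKNOWN_SS

    @property
    def ca(self) -> Atom | None:
        return self.atoms.get("CA")

    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)


@dataclass
class ProteinStructure:
    id: str
    chains: list[str]
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]


def read_structure(path: str | Path, model_index: int = 0) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Only amino-acid ATOM records of one model are kept: waters and hetero
    ligands are excluded, alternate locations resolve to the highest
    occupancy conformer (Biopython's default), and nonstandard residues map
    to one-letter code 'X'.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path}: no models found")
    if model_index >= len(models):
        raise StructureParseError(
            f"{path}: model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    residues: list[Residue] = []
    chains: list[str] = []
    for chain in model:
        for res in chain:
            hetflag, seq_index, _icode = res.id
            if hetflag.strip():  # water or hetero ligand
                continue
            name3 = res.get_resname().strip()
            code1 = THREE_TO_ONE.get(name3, "X")
            atoms = {}
            for atom in res:
                coord = atom.get_coord()
                if not np.all(np.isfinite(coord)):
                    continue
                atoms[atom.get_name()] = Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    coord=np.asarray(coord, dtype=float),
                )
            if not atoms:
                continue
            if chain.id not in chains:
                chains.append(chain.id)
            residues.append(
                Residue(
                    chain_id=chain.id,
                    seq_index=int(seq_index),
                    name3=name3,
                    code1=code1,
                    atoms=atoms,
                )
            )
    if not residues:
        raise EmptyStructureError(f"{path}: no amino-acid residues after filtering")
    return ProteinStructure(id=path.stem, chains=chains, residues=residues)


def write_pdb(s: ProteinStructure, path: str | Path, bfactors: dict[tuple[str, int], float] | None = None) -> None:
    """Write the structure as minimal PDB ATOM records.

    ``bfactors`` maps (chain_id, seq_index) to a temperature-factor value
    written for every atom of that residue (default 0.00).
    """
    path = Path(path)
    lines = []
    serial = 1
    for res in s.residues:
        b = 0.0 if bfactors is None else float(bfactors.get(res.key(), 0.0))
        for atom in res.atoms.values():
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.name3:<3s} {res.chain_id:1s}"
                f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_ss_annotation(path: str | Path) -> dict[tuple[str, int], str]:
    """Read the 2-column secondary-structure TSV dialect.

    Each non-comment line is ``chain:resnum<TAB>ss8`` with ss8 one of the
    eight DSSP states or '-' (mapped to coil).
    """
    mapping: dict[tuple[str, int], str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            key_part, ss = line.split("\t")
            chain, resnum = key_part.split(":")
            ss = ss.strip().upper()
            if ss == "-":
                ss = "C"
            if ss not in SS8_STATES:
                raise ValueError(f"unknown state {ss!r}")
            mapping[(chain, int(resnum))] = ss
        except ValueError as exc:
            raise StructureParseError(
                f"{path}:{lineno}: malformed annotation line ({exc})"
            ) from exc
    return mapping


def _fallback_ss(s: ProteinStructure) -> dict[tuple[str, int], str]:
    """Assign {H, E, C} from C-alpha virtual distances, per chain."""
    labels: dict[tuple[str, int], str] = {}
    for chain in s.chains:
        residues = s.chain_residues(chain)
        ca = [r.ca.coord if r.ca is not None else None for r in residues]
        n = len(residues)
        lab = ["C"] * n

        def dist(i: int, j: int) -> float | None:
            if ca[i] is None or ca[j] is None:
                return None
            return float(np.linalg.norm(ca[i] - ca[j]))

        lo, hi = HELIX_D13_RANGE
        # Helix: four consecutive i->i+3 distances inside the helical window
        # mark residues i..i+6.
        for i in range(n - 6):
            ok = True
            for j in range(i, i + 4):
                d = dist(j, j + 3)
                if d is None or not (lo <= d <= hi):
                    ok = False
                    break
            if ok:
                for k in range(i, i + 7):
                    lab[k] = "H"
        # Strand: locally extended i->i+2 distances over a 3-window, only on
        # residues not already helical.
        for i in range(n - 3):
            d0, d1 = dist(i, i + 2), dist(i + 1, i + 3)
            if d0 is not None and d1 is not None and d0 > STRAND_D02_MIN and d1 > STRAND_D02_MIN:
                for k in range(i, i + 4):
                    if lab[k] != "H":
                        lab[k] = "E"
        for r, l in zip(residues, lab):
            labels[r.key()] = l
    return labels


def assign_secondary_structure(
    s: ProteinStructure, external: str | Path | dict[tuple[str, int], str] | None = None
) -> ProteinStructure:
    """Fill ``ss8`` on every residue, in place, and return the structure.

    With an external annotation (file path or mapping) labels are copied
    verbatim; every annotation key must exist in the structure.  Without
    one, the geometry fallback assigns only {H, E, C}.
    """
    if external is not None:
        mapping = external if isinstance(external, dict) else read_ss_annotation(external)
        known = {r.key() for r in s.residues}
        unknown = set(mapping) - known
        if unknown:
            raise AnnotationKeyError(
                f"annotation references residues absent from structure: {sorted(unknown)[:5]}"
            )
        for r in s.residues:
            r.ss8 = mapping.get(r.key(), "C")
    else:
        labels = _fallback_ss(s)
        for r in s.residues:
            r.ss8 = labels[r.key()]
    return s
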