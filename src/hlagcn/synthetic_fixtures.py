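"""Synthetic structures, peptides and affinity data with planted signal.

Everything here is generated programmatically and seed-deterministic: an
ideal alpha-helical toy structure (with just enough backbone and side-chain
pseudo-atoms to exercise every bond detector), random peptides, and affinity
datasets whose transformed score follows a planted, recoverable rule

    score = 0.3 + effect_size * 1[peptide[anchor] in favored] + N(0, noise_sd)

clamped to [0, 1] and converted back to IC50 by the inverse log50k
transform.  The planted anchor position and favored residue set are the
ground truth against which model training and attribution are validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import STANDARD_AA, ONE_TO_THREE
from .errors import ContractError
from .gcn_model import AffinityRecord, score_to_ic50
from .structure_io import Atom, ProteinStructure, Residue, assign_secondary_structure, write_pdb

HELIX_RADIUS = 2.3       # Angstrom
HELIX_RISE = 1.5         # Angstrom per residue
HELIX_TWIST = 100.0      # degrees per residue
BACKBONE_OFFSET = 1.25   # CA->C and N<-CA displacement along the trace
CARBONYL_LENGTH = 1.23
DISULFIDE_SG_SG = 2.04
IONIC_N_O = 3.5


@dataclass(frozen=True)
class PlantedRule:
    """The recoverable binding rule planted into generated datasets."""

    anchor_position: int = 2           # 1-based peptide index
    favored_residues: frozenset[str] = frozenset("FYW")
    pocket_residue_index: int = 15     # structure node carrying the variant rule
    effect_size: float = 0.4           # transformed-score units
    noise_sd: float = 0.05
    seed: int = 0
    base_score: float = 0.3

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ContractError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be non-negative")


def gen_helix_structure(
    n_res: int,
    seq: str | None = None,
    seed: int = 0,
    disulfide_pairs: tuple[tuple[int, int], ...] = (),
    ionic_pairs: tuple[tuple[int, int], ...] = (),
    chain_id: str = "A",
    structure_id: str = "synthetic-helix",
) -> ProteinStructure:
    """Ideal alpha-helical toy structure (synthetic, not a real protein).

    C-alpha trace on a helix (radius 2.3 A, rise 1.5 A, 100 deg/residue)
    with backbone N, C, O synthesized along the trace.  ``disulfide_pairs``
    (0-based residue indices, both CYS) get SG atoms 2.04 A apart;
    ``ionic_pairs`` (LYS index, GLU index) get NZ/OE1 atoms 3.5 A apart.
    """
    if n_res < 5:
        raise ContractError(f"helix fixture needs >= 5 residues, got {n_res}")
    rng = np.random.default_rng(seed)
    if seq is None:
        seq = "".join(rng.choice(list(STANDARD_AA), size=n_res))
    if len(seq) != n_res:
        raise ContractError(f"seq length {len(seq)} != n_res {n_res}")
    seq = seq.upper()
    for i, j in disulfide_pairs:
        if seq[i] != "C" or seq[j] != "C":
            raise ContractError(f"disulfide pair ({i},{j}) requires CYS at both positions")
    for i, j in ionic_pairs:
        if seq[i] != "K" or seq[j] != "E":
            raise ContractError(f"ionic pair ({i},{j}) requires LYS at i and GLU at j")

    theta = np.deg2rad(HELIX_TWIST) * np.arange(n_res)
    ca = np.stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * np.arange(n_res),
        ],
        axis=1,
    )
    # unit direction of the trace at each residue
    fwd = np.zeros_like(ca)
    fwd[:-1] = ca[1:] - ca[:-1]
    fwd[-1] = fwd[-2]
    fwd /= np.linalg.norm(fwd, axis=1, keepdims=True)

    residues = []
    for i in range(n_res):
        radial = ca[i] - np.array([0.0, 0.0, ca[i, 2]])
        radial /= np.linalg.norm(radial)
        back = fwd[i - 1] if i > 0 else fwd[i]
        atoms = {
            "N": Atom("N", "N", ca[i] - BACKBONE_OFFSET * back),
            "CA": Atom("CA", "C", ca[i]),
            "C": Atom("C", "C", ca[i] + BACKBONE_OFFSET * fwd[i]),
        }
        atoms["O"] = Atom("O", "O", atoms["C"].coord + CARBONYL_LENGTH * radial)
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=i + 1,
                name3=ONE_TO_THREE[seq[i]],
                code1=seq[i],
                atoms=atoms,
            )
        )

    def _place_pair(i: int, j: int, name_i: str, name_j: str, elem_i: str, elem_j: str, gap: float):
        mid = 0.5 * (ca[i] + ca[j])
        v = ca[j] - ca[i]
        v /= np.linalg.norm(v)
        residues[i].atoms[name_i] = Atom(name_i, elem_i, mid - 0.5 * gap * v)
        residues[j].atoms[name_j] = Atom(name_j, elem_j, mid + 0.5 * gap * v)

    for i, j in disulfide_pairs:
        _place_pair(i, j, "SG", "SG", "S", "S", DISULFIDE_SG_SG)
    for i, j in ionic_pairs:
        _place_pair(i, j, "NZ", "OE1", "N", "O", IONIC_N_O)

    return ProteinStructure(id=structure_id, chains=[chain_id], residues=residues)


def fixture_hla_structure(n_res: int = 30, seed: int = 0) -> ProteinStructure:
    """The default HLA stand-in: a helix with secondary structure assigned."""
    s = gen_helix_structure(n_res, seed=seed, structure_id=f"synthetic-hla-{seed}")
    return assign_secondary_structure(s)


def gen_affinity_dataset(
    n_pairs: int,
    rule: PlantedRule,
    peptide_len: int = 9,
    seed: int | None = None,
    hla_id: str = "SYN-HLA-01",
) -> tuple[list[AffinityRecord], dict]:
    """Random peptides with affinities from the planted anchor rule.

    Returns (records, ground_truth); the records carry IC50 nM obtained by
    the inverse log50k transform of the clamped score, and the ground truth
    names the causal peptide position, favored residues and pocket node.
    """
    if n_pairs < 10:
        raise ContractError(f"need at least 10 pairs, got {n_pairs}")
    if not (1 <= rule.anchor_position <= peptide_len):
        raise ContractError("anchor_position outside peptide length")
    rng = np.random.default_rng(rule.seed if seed is None else seed)
    records = []
    for _ in range(n_pairs):
        pep = "".join(rng.choice(list(STANDARD_AA), size=peptide_len))
        hit = pep[rule.anchor_position - 1] in rule.favored_residues
        score = rule.base_score + rule.effect_size * hit
        if rule.noise_sd > 0:
            score += rng.normal(0.0, rule.noise_sd)
        score = float(np.clip(score, 0.0, 1.0))
        records.append(
            AffinityRecord(hla_id=hla_id, peptide_seq=pep, ic50_nM=score_to_ic50(score))
        )
    truth = {
        "anchor_position": rule.anchor_position,
        "favored_residues": sorted(rule.favored_residues),
        "pocket_residue_index": rule.pocket_residue_index,
        "effect_size": rule.effect_size,
        "noise_sd": rule.noise_sd,
        "base_score": rule.base_score,
    }
    return records, truth


def gen_structure_rule_dataset(
    n_pairs: int,
    rule: PlantedRule,
    n_structures: int = 6,
    structure_len: int = 30,
    peptide_len: int = 9,
    seed: int | None = None,
) -> tuple[list[AffinityRecord], dict[str, ProteinStructure], dict]:
    """Variant with the signal on the structure side: the score depends on
    whether the pocket residue of the sampled helix is a favored residue."""
    if n_pairs < 10:
        raise ContractError(f"need at least 10 pairs, got {n_pairs}")
    rng = np.random.default_rng(rule.seed if seed is None else seed)
    structures = {}
    pocket_hit = {}
    for k in range(n_structures):
        seq = "".join(rng.choice(list(STANDARD_AA), size=structure_len))
        hit = bool(k % 2)  # half the panel carries the favored pocket
        pocket = rule.favored_residues if hit else set(STANDARD_AA) - rule.favored_residues
        aa = rng.choice(sorted(pocket))
        seq = seq[: rule.pocket_residue_index] + aa + seq[rule.pocket_residue_index + 1:]
        sid = f"SYN-HLA-{k:02d}"
        s = gen_helix_structure(structure_len, seq=seq, seed=rule.seed, structure_id=sid)
        structures[sid] = assign_secondary_structure(s)
        pocket_hit[sid] = hit
    ids = sorted(structures)
    records = []
    for _ in range(n_pairs):
        sid = str(rng.choice(ids))
        pep = "".join(rng.choice(list(STANDARD_AA), size=peptide_len))
        score = rule.base_score + rule.effect_size * pocket_hit[sid]
        if rule.noise_sd > 0:
            score += rng.normal(0.0, rule.noise_sd)
        score = float(np.clip(score, 0.0, 1.0))
        records.append(AffinityRecord(hla_id=sid, peptide_seq=pep, ic50_nM=score_to_ic50(score)))
    truth = {"pocket_residue_index": rule.pocket_residue_index, "pocket_hit": pocket_hit}
    return records, structures, truth


def write_training_table(records, path: str | Path, structure_path: str = "") -> None:
    """Write the TSV dialect consumed by the trainer (deterministic bytes)."""
    lines = ["hla_id\tstructure_path\tpeptide_seq\tic50_nM"]
    for rec in records:
        lines.append(
            f"{rec.hla_id}\t{structure_path}\t{rec.peptide_seq}\t{rec.ic50_nM:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_pairs: int = 200,
    peptide_len: int = 9,
    n_res: int = 30,
    rule: PlantedRule | None = None,
) -> dict:
    """Write the full fixture set: PDB, training TSV, FASTA, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rule = rule or PlantedRule(seed=seed)
    structure = fixture_hla_structure(n_res=n_res, seed=seed)
    records, truth = gen_affinity_dataset(
        n_pairs, rule, peptide_len=peptide_len, seed=seed, hla_id=structure.id
    )
    write_pdb(structure, out / "hla.pdb")
    write_training_table(records, out / "train.tsv", structure_path="hla.pdb")
    with open(out / "peptides.fasta", "w") as fh:
        for i, rec in enumerate(records):
            fh.write(f">pep{i:04d}\n{rec.peptide_seq}\n")
    truth["seed"] = seed
    truth["hla_id"] = structure.id
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
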