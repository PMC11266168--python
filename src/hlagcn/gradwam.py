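"""Gradient-weighted activation mapping (Grad-WAM) for node attribution.

Importance of each node is derived from the activations T of the last
graph-convolution layer of one branch.  With P the (raw) predicted score,
the per-entry coefficients

    alpha = (dP/dT) / (dP/dT + T * d2P/dT2)

weight the ReLU-rectified first partials into per-channel weights
w_c = sum_i alpha_ic * ReLU(dP/dT_ic); the node score is the rectified
weighted activation s_i = ReLU(sum_c w_c T_ic) and omega = sum_c w_c is
reported as a diagnostic.  First partials come from reverse-mode
differentiation of the prediction head; the diagonal second partials from
exact second-order forward-mode jets (for the ReLU head they vanish almost
everywhere, and alpha degrades to 1 under the epsilon-guard).

An occlusion oracle (zero one node's input features, re-predict) and a
B-factor-encoded structure annotation for blue-to-red viewer coloring are
included for validating and visualizing attributions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AnnotationKeyError, ContractError
from .gcn_model import AffinityModel, prepare_graph, readout
from .structure_io import ProteinStructure, write_pdb

ALPHA_EPS = 1e-12


@dataclass
class FeatureMap:
    """Last-layer activations of one branch with exact partials of P."""

    T: np.ndarray        # N x C activations
    grad1: np.ndarray    # dP/dT, same shape
    grad2: np.ndarray    # diagonal d2P/dT2, same shape
    branch: str          # "hla" | "pep"
    other_pooled: np.ndarray  # frozen readout vector of the other branch
    node_ids: list

    def __post_init__(self) -> None:
        if not (self.T.shape == self.grad1.shape == self.grad2.shape):
            raise ContractError("T, grad1, grad2 must share one shape")


@dataclass
class AttributionResult:
    node_ids: list
    raw: np.ndarray
    normalized: np.ndarray
    omega: float
    branch: str


def _pool_coefficients(H: np.ndarray, mode: str) -> np.ndarray:
    """d(readout)/dT as per-entry coefficients (N x C)."""
    n, c = H.shape
    if mode == "mean":
        return np.full((n, c), 1.0 / n)
    if mode == "sum":
        return np.ones((n, c))
    coeff = np.zeros((n, c))  # max: subgradient at the argmax row
    coeff[H.argmax(axis=0), np.arange(c)] = 1.0
    return coeff


def _assemble_z(model: AffinityModel, pooled: np.ndarray, other: np.ndarray, branch: str) -> np.ndarray:
    return np.concatenate([pooled, other] if branch == "hla" else [other, pooled])


def head_value(model: AffinityModel, T: np.ndarray, other_pooled: np.ndarray, branch: str) -> float:
    """Raw prediction as a function of the last-layer activations T.

    This is the function Grad-WAM differentiates; it is also the evaluation
    target for finite-difference checks of the gradients.
    """
    pooled = readout(T, model.config.readout)
    P, _ = model.mlp_forward(_assemble_z(model, pooled, other_pooled, branch))
    return P


def _mlp_grad_z(model: AffinityModel, z: np.ndarray) -> np.ndarray:
    """Reverse-mode dP/dz through the evaluation-mode MLP."""
    pre = []
    h = z
    for l in range(3):
        a = h @ model.weights[f"mlp_W{l}"] + model.weights[f"mlp_b{l}"]
        pre.append(a)
        h = np.maximum(a, 0.0) if l < 2 else a
    d = np.ones(1)
    for l in (2, 1, 0):
        d = d @ model.weights[f"mlp_W{l}"].T
        if l > 0:
            d = d * (pre[l - 1] > 0)
    return d


def _mlp_second_directional(model: AffinityModel, z: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Exact second directional derivatives of P along each column of
    ``directions``, by forward-mode (value, first, second) jets."""
    v = z
    d = directions
    s = np.zeros_like(d)
    for l in range(3):
        W = model.weights[f"mlp_W{l}"]
        v = v @ W + model.weights[f"mlp_b{l}"]
        d = W.T @ d
        s = W.T @ s
        if l < 2:
            mask = (v > 0).astype(float)
            # ReLU jets: y' = 1[v>0] v', y'' = 1[v>0] v'' (exact off the kink)
            v = np.maximum(v, 0.0)
            d = d * mask[:, None]
            s = s * mask[:, None]
    return s[0]


def capture_feature_map(model: AffinityModel, hla, pep, branch: str) -> FeatureMap:
    """Forward pass capturing T of ``branch`` and exact dP/dT, d2P/dT2."""
    if branch not in ("hla", "pep"):
        raise ContractError(f"branch must be 'hla' or 'pep', got {branch!r}")
    cfg = model.config
    acts_h = model.branch_forward("hla", *prepare_graph(hla, cfg))
    acts_p = model.branch_forward("pep", *prepare_graph(pep, cfg))
    T = (acts_h if branch == "hla" else acts_p)[-1]
    other = readout((acts_p if branch == "hla" else acts_h)[-1], cfg.readout)
    pooled = readout(T, cfg.readout)
    z = _assemble_z(model, pooled, other, branch)

    dz = _mlp_grad_z(model, z)
    offset = 0 if branch == "hla" else (z.size - T.shape[1])
    dP_dg = dz[offset: offset + T.shape[1]]
    coeff = _pool_coefficients(T, cfg.readout)
    grad1 = coeff * dP_dg[None, :]

    # Second partials: direction e_(i,c) maps through pooling to
    # coeff[i,c] * e_c in z-space, so d2P/dT_ic^2 = coeff^2 * d2P along e_c.
    directions = np.zeros((z.size, T.shape[1]))
    for c in range(T.shape[1]):
        directions[offset + c, c] = 1.0
    s_per_channel = _mlp_second_directional(model, z, directions)
    grad2 = coeff**2 * s_per_channel[None, :]

    node_ids = list(hla.node_ids) if branch == "hla" else list(range(pep.n_nodes))
    return FeatureMap(T=T, grad1=grad1, grad2=grad2, branch=branch,
                      other_pooled=other, node_ids=node_ids)


def alpha_coefficients(fm: FeatureMap, eps: float = ALPHA_EPS) -> np.ndarray:
    """Per-entry alpha = g1 / (g1 + T*g2); degenerate denominators give 1."""
    denom = fm.grad1 + fm.T * fm.grad2
    alpha = np.ones_like(fm.grad1)
    ok = np.abs(denom) >= eps
    alpha[ok] = fm.grad1[ok] / denom[ok]
    return alpha


def gradwam_scores(model: AffinityModel, hla, pep, branch: str) -> AttributionResult:
    """Per-node Grad-WAM attribution for one branch of one prediction."""
    fm = capture_feature_map(model, hla, pep, branch)
    alpha = alpha_coefficients(fm)
    w = (alpha * np.maximum(fm.grad1, 0.0)).sum(axis=0)
    raw = np.maximum(fm.T @ w, 0.0)
    omega = float(w.sum())

    span = raw.max() - raw.min()
    if span <= 0:
        warnings.warn(
            "all node scores equal; normalized attribution set to zeros",
            stacklevel=2,
        )
        normalized = np.zeros_like(raw)
    else:
        normalized = (raw - raw.min()) / span
    return AttributionResult(
        node_ids=fm.node_ids, raw=raw, normalized=normalized, omega=omega, branch=branch
    )


def occlusion_scores(model: AffinityModel, hla, pep, branch: str) -> np.ndarray:
    """Occlusion oracle: delta P from zeroing each node's input features."""
    cfg = model.config
    hp, pp = prepare_graph(hla, cfg), prepare_graph(pep, cfg)
    p_full = model.forward_raw(hp, pp)
    A, X = (hp if branch == "hla" else pp)
    # Occlusion acts in the model's input space: with feature
    # standardization on, a zeroed standardized row corresponds to the raw
    # training-mean feature vector.
    fill = model.feature_stats.get(f"{branch}_mu", np.zeros(X.shape[1]))
    deltas = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        X_occ = X.copy()
        X_occ[i, :] = fill
        occluded = (A, X_occ)
        if branch == "hla":
            deltas[i] = p_full - model.forward_raw(occluded, pp)
        else:
            deltas[i] = p_full - model.forward_raw(hp, occluded)
    return deltas


def residue_attribution(attr: AttributionResult, pep_graph) -> dict[int, float]:
    """Collapse a peptide-branch attribution to per-residue scores (max over
    the residue's atoms)."""
    if attr.branch != "pep":
        raise ContractError("residue_attribution expects a peptide-branch result")
    scores: dict[int, float] = {}
    for idx, (pos, _aa) in zip(attr.node_ids, pep_graph.atom_to_residue):
        scores[pos] = max(scores.get(pos, -np.inf), float(attr.raw[idx]))
    return scores


def annotate_structure(s: ProteinStructure, attr: AttributionResult, path: str | Path) -> None:
    """Write a PDB with B-factors = 100 x normalized score for coloring."""
    keys = {r.key() for r in s.residues}
    bfactors = {}
    for node_id, value in zip(attr.node_ids, attr.normalized):
        key = (node_id[0], int(node_id[1]))
        if key not in keys:
            raise AnnotationKeyError(f"attributed residue {key} absent from structure")
        bfactors[key] = 100.0 * float(value)
    write_pdb(s, path, bfactors=bfactors)


def attribution_to_csv(attr: AttributionResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "raw", "normalized"])
        for node_id, r, n in zip(attr.node_ids, attr.raw, attr.normalized):
            label = f"{node_id[0]}:{node_id[1]}" if isinstance(node_id, tuple) else str(node_id)
            writer.writerow([label, f"{r:.6g}", f"{n:.6g}"])
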