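"""Twin-GCN affinity regressor and the IC50 score transform.

The model embeds the HLA residue graph and the peptide atom graph with two
independent stacks of graph-convolution layers

    H^(l+1) = ReLU( D^-1/2 (A + I) D^-1/2  H^(l)  W^(l+1) ),

pools each stack with a permutation-invariant readout, concatenates the two
graph vectors and regresses the log50k-transformed affinity score through a
three-layer MLP (ReLU + dropout 0.1 after the first two layers).  Training
minimizes mean squared error with Adam; every source of randomness
(initialization, shuffling, dropout) is driven by one seed.

All linear algebra is plain numpy: the graphs are small (hundreds of nodes)
and an explicit implementation keeps forward, backward and the second-order
derivatives used by the attribution module in one place.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hla_graph as hg
from . import peptide_graph as pg
from .errors import ContractError

LOG_50K = math.log(50000.0)
# Transformed score of the 500 nM binder threshold, held at full precision.
BINDER_SCORE_CUTOFF = 1.0 - math.log(500.0) / LOG_50K


def ic50_to_score(ic50_nM: float) -> float:
    """Log50k transform: 1 - ln(IC50)/ln(50000), clamped to [0, 1]."""
    if ic50_nM <= 0:
        raise ContractError(f"IC50 must be positive, got {ic50_nM}")
    return float(np.clip(1.0 - math.log(ic50_nM) / LOG_50K, 0.0, 1.0))


def score_to_ic50(score: float) -> float:
    """Inverse transform: IC50 = 50000^(1 - score)."""
    return float(math.exp((1.0 - score) * LOG_50K))


def classify_binder(score: float) -> str:
    """Binder iff the transformed score strictly exceeds the 500 nM cutoff."""
    if not (0.0 <= score <= 1.0):
        raise ContractError(f"score {score} outside [0, 1]")
    return "binder" if score > BINDER_SCORE_CUTOFF else "nonbinder"


@dataclass
class AffinityRecord:
    """One HLA-peptide measurement, as IC50 (nM) or transformed score."""

    hla_id: str
    peptide_seq: str
    ic50_nM: float | None = None
    transformed_score: float | None = None

    def __post_init__(self) -> None:
        if (self.ic50_nM is None) == (self.transformed_score is None):
            raise ContractError(
                "exactly one of ic50_nM / transformed_score must be present"
            )
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ContractError("ic50_nM must be positive")

    def score(self) -> float:
        if self.transformed_score is not None:
            return float(self.transformed_score)
        return ic50_to_score(self.ic50_nM)


@dataclass
class GCNConfig:
    hla_layer_dims: tuple[int, ...] = (32, 32)
    pep_layer_dims: tuple[int, ...] = (48, 48, 48, 48, 48, 48)
    readout: str = "mean"
    mlp_dims: tuple[int, ...] = (64, 32, 1)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    n_epochs: int = 150
    batch_size: int = 32
    seed: int = 0
    edge_weight_mode: str = "binary"
    gcn_bias: bool = True
    weight_decay: float = 1e-4
    standardize_features: bool = True
    hla_input_dim: int = hg.FEATURE_WIDTH
    pep_input_dim: int = pg.FEATURE_WIDTH

    def __post_init__(self) -> None:
        self.hla_layer_dims = tuple(self.hla_layer_dims)
        self.pep_layer_dims = tuple(self.pep_layer_dims)
        self.mlp_dims = tuple(self.mlp_dims)
        if not (0.0 <= self.dropout < 1.0):
            raise ContractError("dropout must be in [0, 1)")
        if not self.hla_layer_dims or not self.pep_layer_dims:
            raise ContractError("each GCN branch needs at least one layer")
        if len(self.mlp_dims) != 3 or self.mlp_dims[-1] != 1:
            raise ContractError("mlp_dims must list exactly 3 layer widths ending in 1")
        if self.readout not in ("mean", "sum", "max"):
            raise ContractError(f"unknown readout {self.readout!r}")
        if self.edge_weight_mode not in ("binary", "distance_inverse"):
            raise ContractError(f"unknown edge_weight_mode {self.edge_weight_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "GCNConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def normalize_adjacency(edges, n_nodes: int, edge_weight_mode: str = "binary") -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops.

    A-hat = A + I; D-hat its diagonal degree; returns D^-1/2 A-hat D^-1/2.
    With ``distance_inverse``, off-diagonal entries of A are 1/distance
    (edges without a distance attribute weigh 1).
    """
    A = np.zeros((n_nodes, n_nodes))
    for e in edges:
        if not (0 <= e.i < n_nodes and 0 <= e.j < n_nodes):
            raise ContractError(f"edge ({e.i},{e.j}) out of range for N={n_nodes}")
        if edge_weight_mode == "distance_inverse":
            w = 1.0 / getattr(e, "distance", 1.0)
        else:
            w = 1.0
        A[e.i, e.j] = max(A[e.i, e.j], w)
        A[e.j, e.i] = A[e.i, e.j]
    A_hat = A + np.eye(n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_layer(H: np.ndarray, A_norm: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(A_norm @ H @ W)."""
    if H.shape[0] != A_norm.shape[0] or H.shape[1] != W.shape[0]:
        raise ContractError(
            f"shape mismatch: A {A_norm.shape}, H {H.shape}, W {W.shape}"
        )
    return _relu(A_norm @ H @ W)


def readout(H: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Permutation-invariant pooling of node embeddings."""
    if H.shape[0] < 1:
        raise ContractError("readout needs at least one node")
    if mode == "mean":
        return H.mean(axis=0)
    if mode == "sum":
        return H.sum(axis=0)
    if mode == "max":
        return H.max(axis=0)
    raise ContractError(f"unknown readout {mode!r}")


@dataclass
class AffinityModel:
    config: GCNConfig
    weights: dict[str, np.ndarray]
    training_history: list[float] = field(default_factory=list)
    # Per-branch feature mean/scale fitted on the training set; applied to
    # H^0 before the first convolution when standardize_features is on.
    feature_stats: dict[str, np.ndarray] = field(default_factory=dict)

    def standardized(self, branch: str, X: np.ndarray) -> np.ndarray:
        mu = self.feature_stats.get(f"{branch}_mu")
        if mu is None:
            return X
        return (X - mu) / self.feature_stats[f"{branch}_sd"]

    # -- parameter bookkeeping -------------------------------------------

    @staticmethod
    def _layer_dims(config: GCNConfig) -> dict[str, list[tuple[int, int]]]:
        hla = list(zip((config.hla_input_dim,) + config.hla_layer_dims, config.hla_layer_dims))
        pep = list(zip((config.pep_input_dim,) + config.pep_layer_dims, config.pep_layer_dims))
        concat = config.hla_layer_dims[-1] + config.pep_layer_dims[-1]
        mlp = list(zip((concat,) + config.mlp_dims[:-1], config.mlp_dims))
        return {"hla": hla, "pep": pep, "mlp": mlp}

    @classmethod
    def initialize(cls, config: GCNConfig, rng: np.random.Generator | None = None) -> "AffinityModel":
        """Glorot-uniform weights, zero biases, seeded by config.seed."""
        rng = rng or np.random.default_rng(config.seed)
        dims = cls._layer_dims(config)
        w: dict[str, np.ndarray] = {}

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        for branch in ("hla", "pep"):
            for l, (fi, fo) in enumerate(dims[branch]):
                w[f"{branch}_{l}"] = glorot(fi, fo)
                if config.gcn_bias:
                    w[f"{branch}_b{l}"] = np.zeros(fo)
        for l, (fi, fo) in enumerate(dims["mlp"]):
            w[f"mlp_W{l}"] = glorot(fi, fo)
            w[f"mlp_b{l}"] = np.zeros(fo)
        return cls(config=config, weights=w)

    def branch_weights(self, branch: str) -> list[np.ndarray]:
        n = len(self.config.hla_layer_dims if branch == "hla" else self.config.pep_layer_dims)
        return [self.weights[f"{branch}_{l}"] for l in range(n)]

    # -- forward passes ---------------------------------------------------

    def branch_forward(self, branch: str, A_norm: np.ndarray, X: np.ndarray) -> list[np.ndarray]:
        """All layer activations [X, H1, ..., H_last] of one branch."""
        expected = self.config.hla_input_dim if branch == "hla" else self.config.pep_input_dim
        if X.shape[1] != expected:
            raise ContractError(
                f"{branch} branch: feature width {X.shape[1]} != configured {expected}"
            )
        X = self.standardized(branch, X)
        acts = [X]
        H = X
        for l, W in enumerate(self.branch_weights(branch)):
            # Kipf-style convolution; the learned bias (on by default, as in
            # standard GCN library layers) is disabled by config.gcn_bias.
            M = A_norm @ H @ W
            if self.config.gcn_bias:
                M = M + self.weights[f"{branch}_b{l}"]
            H = _relu(M)
            acts.append(H)
        return acts

    def mlp_forward(
        self, z: np.ndarray, dropout_masks: list[np.ndarray] | None = None
    ) -> tuple[float, list[np.ndarray]]:
        """MLP head on the concatenated graph vector; returns (P, hidden acts).

        ``dropout_masks`` (training only) are inverted-dropout multipliers
        applied after the ReLU of the first two layers.
        """
        hidden = []
        h = z
        for l in range(3):
            h = h @ self.weights[f"mlp_W{l}"] + self.weights[f"mlp_b{l}"]
            if l < 2:
                h = _relu(h)
                if dropout_masks is not None:
                    h = h * dropout_masks[l]
                hidden.append(h)
        return float(h[0]), hidden

    def forward_raw(self, hla_prep, pep_prep) -> float:
        """Deterministic evaluation-mode forward; unclamped output."""
        gh = readout(self.branch_forward("hla", *hla_prep)[-1], self.config.readout)
        gp = readout(self.branch_forward("pep", *pep_prep)[-1], self.config.readout)
        P, _ = self.mlp_forward(np.concatenate([gh, gp]))
        return P


def prepare_graph(graph, config: GCNConfig) -> tuple[np.ndarray, np.ndarray]:
    """(normalized adjacency, feature matrix) of a residue or atom graph."""
    A = normalize_adjacency(graph.edges, graph.n_nodes, config.edge_weight_mode)
    return A, np.asarray(graph.X, dtype=float)


def predict(model: AffinityModel, hla, pep) -> float:
    """Transformed affinity score in [0, 1] for one HLA-peptide pair."""
    raw = model.forward_raw(prepare_graph(hla, model.config), prepare_graph(pep, model.config))
    return float(np.clip(raw, 0.0, 1.0))


# -- training -------------------------------------------------------------


def _backward_sample(model, hla_prep, pep_prep, y, dropout_masks, grads):
    """Accumulate d(P - y)^2/dW for one pair; returns squared error."""
    cfg = model.config
    acts_h = model.branch_forward("hla", *hla_prep)
    acts_p = model.branch_forward("pep", *pep_prep)
    gh = readout(acts_h[-1], cfg.readout)
    gp = readout(acts_p[-1], cfg.readout)
    z = np.concatenate([gh, gp])

    # MLP forward with caches
    pre, post = [], []
    h = z
    for l in range(3):
        a = h @ model.weights[f"mlp_W{l}"] + model.weights[f"mlp_b{l}"]
        pre.append(a)
        if l < 2:
            h = _relu(a) * dropout_masks[l]
        else:
            h = a
        post.append(h)
    P = float(h[0])
    err = P - y

    # MLP backward
    d = np.array([2.0 * err])
    inputs = [z, post[0], post[1]]
    for l in (2, 1, 0):
        grads[f"mlp_W{l}"] += np.outer(inputs[l], d)
        grads[f"mlp_b{l}"] += d
        d = d @ model.weights[f"mlp_W{l}"].T
        if l > 0:
            d = d * (pre[l - 1] > 0) * dropout_masks[l - 1]
    dgh, dgp = d[: gh.size], d[gh.size:]

    # branch backward
    for branch, acts, A, dG in (("hla", acts_h, hla_prep[0], dgh), ("pep", acts_p, pep_prep[0], dgp)):
        H_last = acts[-1]
        n = H_last.shape[0]
        if cfg.readout == "mean":
            dH = np.repeat(dG[None, :] / n, n, axis=0)
        elif cfg.readout == "sum":
            dH = np.repeat(dG[None, :], n, axis=0)
        else:  # max: route to argmax rows
            dH = np.zeros_like(H_last)
            dH[H_last.argmax(axis=0), np.arange(H_last.shape[1])] = dG
        Ws = model.branch_weights(branch)
        for l in range(len(Ws) - 1, -1, -1):
            dM = dH * (acts[l + 1] > 0)
            AH = A @ acts[l]
            grads[f"{branch}_{l}"] += AH.T @ dM
            if cfg.gcn_bias:
                grads[f"{branch}_b{l}"] += dM.sum(axis=0)
            dH = A.T @ (dM @ Ws[l].T)
    return err * err


def train(dataset, config: GCNConfig, validation=None) -> AffinityModel:
    """Fit the regressor on (ResidueGraph, AtomGraph, score) triples.

    Mini-batch Adam on the mean squared error of the raw MLP output against
    the transformed scores; per-epoch training MSE is recorded in
    ``model.training_history``.  Repeated graph objects (a shared HLA
    structure, duplicate peptides) are prepared once.
    """
    if not dataset:
        raise ContractError("empty training dataset")
    for _, _, y in dataset:
        if not (0.0 <= y <= 1.0):
            raise ContractError(f"target score {y} outside [0, 1]")

    rng = np.random.default_rng(config.seed)
    model = AffinityModel.initialize(config, rng)

    if config.standardize_features:
        for branch, col in (("hla", 0), ("pep", 1)):
            uniq = {id(row[col]): row[col] for row in dataset}
            X_all = np.vstack([g.X for g in uniq.values()])
            sd = X_all.std(axis=0)
            sd[sd < 1e-8] = 1.0
            model.feature_stats[f"{branch}_mu"] = X_all.mean(axis=0)
            model.feature_stats[f"{branch}_sd"] = sd

    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def prep(graph):
        key = id(graph)
        if key not in cache:
            cache[key] = prepare_graph(graph, config)
        return cache[key]

    samples = [(prep(h), prep(p), float(y)) for h, p, y in dataset]

    m = {k: np.zeros_like(v) for k, v in model.weights.items()}
    v = {k: np.zeros_like(w) for k, w in model.weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    keep = 1.0 - config.dropout
    mlp_hidden = [model.config.mlp_dims[0], model.config.mlp_dims[1]]

    for _epoch in range(config.n_epochs):
        order = rng.permutation(len(samples))
        epoch_se, epoch_n = 0.0, 0
        for start in range(0, len(samples), config.batch_size):
            batch = [samples[i] for i in order[start: start + config.batch_size]]
            grads = {k: np.zeros_like(w) for k, w in model.weights.items()}
            for hp, pp, y in batch:
                if config.dropout > 0:
                    masks = [
                        (rng.random(d) < keep).astype(float) / keep for d in mlp_hidden
                    ]
                else:
                    masks = [np.ones(d) for d in mlp_hidden]
                epoch_se += _backward_sample(model, hp, pp, y, masks, grads)
                epoch_n += 1
            t += 1
            for k in model.weights:
                g = grads[k] / len(batch)
                if config.weight_decay > 0 and "_b" not in k:  # decay weights, not biases
                    g = g + config.weight_decay * model.weights[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                m_hat = m[k] / (1 - beta1**t)
                v_hat = v[k] / (1 - beta2**t)
                model.weights[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        model.training_history.append(epoch_se / epoch_n)
    return model


# -- persistence and tables ----------------------------------------------


def save_model(model: AffinityModel, path: str | Path) -> None:
    """Single-file checkpoint: config JSON + weights + training history."""
    arrays = {f"weight__{k}": v for k, v in model.weights.items()}
    arrays.update({f"stats__{k}": v for k, v in model.feature_stats.items()})
    np.savez(
        path,
        config_json=json.dumps(asdict(model.config)),
        training_history=np.array(model.training_history),
        **arrays,
    )


def load_model(path: str | Path) -> AffinityModel:
    with np.load(path, allow_pickle=False) as data:
        config = GCNConfig.from_dict(json.loads(str(data["config_json"])))
        weights = {
            k[len("weight__"):]: np.array(data[k])
            for k in data.files
            if k.startswith("weight__")
        }
        stats = {
            k[len("stats__"):]: np.array(data[k])
            for k in data.files
            if k.startswith("stats__")
        }
        history = [float(x) for x in data["training_history"]]
    return AffinityModel(
        config=config, weights=weights, training_history=history, feature_stats=stats
    )


TRAINING_COLUMNS = ("hla_id", "structure_path", "peptide_seq", "ic50_nM")


def read_training_table(path: str | Path) -> list[AffinityRecord]:
    """Read the training TSV (hla_id, structure_path, peptide_seq, ic50_nM
    or transformed_score); structure_path may be empty when graphs are
    supplied separately."""
    df = pd.read_csv(path, sep="\t")
    has_ic50 = "ic50_nM" in df.columns
    has_score = "transformed_score" in df.columns
    if not (has_ic50 or has_score):
        raise ContractError(
            f"{path}: need an ic50_nM or transformed_score column, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AffinityRecord(
                hla_id=str(row.hla_id),
                peptide_seq=str(row.peptide_seq),
                ic50_nM=float(row.ic50_nM) if has_ic50 else None,
                transformed_score=None if has_ic50 else float(row.transformed_score),
            )
        )
    return records


def records_to_dataset(records, hla_graphs: dict[str, hg.ResidueGraph]):
    """(ResidueGraph, AtomGraph, score) triples; peptide graphs are cached."""
    pep_cache: dict[str, pg.AtomGraph] = {}
    dataset = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # atypical peptide lengths are fine here
        for rec in records:
            if rec.hla_id not in hla_graphs:
                raise ContractError(f"no HLA graph provided for id {rec.hla_id!r}")
            if rec.peptide_seq not in pep_cache:
                pep_cache[rec.peptide_seq] = pg.build_peptide_graph(rec.peptide_seq)
            dataset.append((hla_graphs[rec.hla_id], pep_cache[rec.peptide_seq], rec.score()))
    return dataset
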