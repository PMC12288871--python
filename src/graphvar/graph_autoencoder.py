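"""Graph autoencoders for protein graphs, trained by edge reconstruction.

Two encoders share one architecture family:

* ``GCEncoder`` (residue scope): stacked graph-convolution layers — symmetric
  degree-normalised propagation with self-loops — each followed by a
  layer normalisation computed per graph (zero mean / unit variance over all
  of the graph's node activations, then a learned per-channel affine) and a
  ReLU after every layer except the last.
* ``MPNNEncoder`` (atomic scope): the same stack, with an additional linear
  map of the scalar edge feature summed over each node's incident edges.

An inner-product decoder turns pairs of node embeddings into edge
probabilities, ``sigmoid(z_i . z_j)``. Training minimises binary
cross-entropy over positive edges and an equal number of negatively sampled
non-edges, with Adam, mini-batches of whole graphs, and early stopping on
validation edge accuracy (patience in epochs without an increase). Embeddings
of dimension 128 use two layers; dimension 256 uses three.

Everything is plain numpy with hand-derived gradients; graphs are small
enough that dense per-graph activations and sparse adjacency suffice on CPU.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from ._ranking import auroc_rank, average_precision
from .protein_graphs import ProteinGraph

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "GAEModel",
    "TrainHistory",
    "EarlyStopper",
    "SamplingError",
    "encoder_forward",
    "global_mean_pool",
    "inner_product_decode",
    "negative_sample",
    "reconstruction_loss",
    "train_gae",
    "evaluate_gae",
    "save_model",
    "load_model",
]

_LN_EPS = 1e-5
_PROB_CLAMP = 1e-15


class SamplingError(RuntimeError):
    """Raised when negative sampling is impossible (complete graph)."""


@dataclass
class EncoderConfig:
    scope: str
    input_dim: int
    embedding_dim: int = 128
    n_layers: int | None = None
    hidden_dim: int | None = None

    def __post_init__(self):
        if self.scope not in ("residue", "atomic"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.input_dim < 1 or self.embedding_dim < 1:
            raise ValueError("dimensions must be positive")
        if self.n_layers is None:
            # published pairing: dim 128 -> 2 layers, dim 256 -> 3 layers
            self.n_layers = {128: 2, 256: 3}.get(self.embedding_dim, 2)
        if self.hidden_dim is None:
            self.hidden_dim = self.embedding_dim

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim] + [self.hidden_dim] * (self.n_layers - 1) + [self.embedding_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class TrainConfig:
    max_epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.005
    patience: int = 3
    split: tuple = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class GAEModel:
    config: EncoderConfig
    params: dict = field(default_factory=dict)

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


@dataclass
class TrainHistory:
    train_loss: list
    val_accuracy: list
    best_epoch: int
    stopped_epoch: int
    test_auc: float
    test_ap: float


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a validation increase."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self._stalled = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record an epoch's validation value; return True if training should stop."""
        if value > self.best:
            self.best = value
            self.best_epoch = epoch
            self._stalled = 0
        else:
            self._stalled += 1
        return self._stalled >= self.patience


def init_model(config: EncoderConfig, seed: int = 0) -> GAEModel:
    """Seeded Glorot-uniform weights; identity affine for the layer norms."""
    rng = np.random.default_rng(seed)
    params = {}
    for l, (din, dout) in enumerate(config.layer_dims):
        a = np.sqrt(6.0 / (din + dout))
        params[f"W{l}"] = rng.uniform(-a, a, size=(din, dout))
        params[f"b{l}"] = np.zeros(dout)
        params[f"gamma{l}"] = np.ones(dout)
        params[f"beta{l}"] = np.zeros(dout)
        if config.scope == "atomic":
            ae = np.sqrt(6.0 / (1 + dout))
            params[f"we{l}"] = rng.uniform(-ae, ae, size=dout)
            params[f"be{l}"] = np.zeros(dout)
    return GAEModel(config=config, params=params)


# ---------------------------------------------------------------------------
# graph preparation

def _normalized_adjacency(n_nodes: int, edges: np.ndarray) -> sp.csr_matrix:
    """Symmetric-normalised adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    if len(edges):
        i, j = edges[:, 0], edges[:, 1]
        data = np.ones(2 * len(edges))
        a = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n_nodes, n_nodes),
        )
    else:
        a = sp.coo_matrix((n_nodes, n_nodes))
    a = (a + sp.eye(n_nodes)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    return sp.diags(dinv) @ a @ sp.diags(dinv)


class _PreparedGraph:
    """Cached tensors for one graph: Â, features, edges, edge-feature sums."""

    def __init__(self, graph: ProteinGraph):
        self.graph = graph
        self.n = graph.n_nodes
        self.x = np.asarray(graph.node_features, dtype=float)
        self.edges = np.asarray(graph.edges, dtype=int).reshape(-1, 2)
        self.a_hat = _normalized_adjacency(self.n, self.edges)
        self.esum = np.zeros(self.n)
        self.edeg = np.zeros(self.n)
        if graph.edge_features is not None and len(self.edges):
            ef = np.asarray(graph.edge_features, dtype=float)
            np.add.at(self.esum, self.edges[:, 0], ef)
            np.add.at(self.esum, self.edges[:, 1], ef)
            np.add.at(self.edeg, self.edges[:, 0], 1.0)
            np.add.at(self.edeg, self.edges[:, 1], 1.0)
        self._non_edges = None

    def non_edges(self) -> np.ndarray:
        if self._non_edges is None:
            n = self.n
            adj = np.zeros((n, n), dtype=bool)
            if len(self.edges):
                adj[self.edges[:, 0], self.edges[:, 1]] = True
                adj[self.edges[:, 1], self.edges[:, 0]] = True
            iu, ju = np.triu_indices(n, k=1)
            mask = ~adj[iu, ju]
            self._non_edges = np.stack([iu[mask], ju[mask]], axis=1)
        return self._non_edges


# ---------------------------------------------------------------------------
# forward / backward

def _forward(prep: _PreparedGraph, model: GAEModel, want_cache: bool = False):
    cfg = model.config
    mpnn = cfg.scope == "atomic"
    h = prep.x
    caches = []
    n_layers = cfg.n_layers
    for l in range(n_layers):
        m = prep.a_hat @ h
        z = m @ model.params[f"W{l}"] + model.params[f"b{l}"]
        if mpnn:
            z = z + prep.esum[:, None] * model.params[f"we{l}"] + prep.edeg[:, None] * model.params[f"be{l}"]
        mu = z.mean()
        var = z.var()
        zn = (z - mu) / np.sqrt(var + _LN_EPS)
        out = zn * model.params[f"gamma{l}"] + model.params[f"beta{l}"]
        last = l == n_layers - 1
        h_next = out if last else np.maximum(out, 0.0)
        if want_cache:
            caches.append({"m": m, "zn": zn, "var": var, "out": out})
        h = h_next
    return (h, caches) if want_cache else h


def _backward(prep: _PreparedGraph, model: GAEModel, caches, d_out: np.ndarray) -> dict:
    cfg = model.config
    mpnn = cfg.scope == "atomic"
    grads = {}
    dh = d_out
    for l in range(cfg.n_layers - 1, -1, -1):
        c = caches[l]
        if l != cfg.n_layers - 1:
            dh = dh * (c["out"] > 0)
        zn = c["zn"]
        grads[f"gamma{l}"] = (dh * zn).sum(axis=0)
        grads[f"beta{l}"] = dh.sum(axis=0)
        dzn = dh * model.params[f"gamma{l}"]
        # layer-norm backward, statistics over the whole n x d activation matrix
        dz = (dzn - dzn.mean() - zn * (dzn * zn).mean()) / np.sqrt(c["var"] + _LN_EPS)
        grads[f"W{l}"] = c["m"].T @ dz
        grads[f"b{l}"] = dz.sum(axis=0)
        if mpnn:
            grads[f"we{l}"] = prep.esum @ dz
            grads[f"be{l}"] = prep.edeg @ dz
        dm = dz @ model.params[f"W{l}"].T
        dh = prep.a_hat @ dm  # Â is symmetric
    return grads


# ---------------------------------------------------------------------------
# public operations

def encoder_forward(graph: ProteinGraph, model: GAEModel) -> np.ndarray:
    """Node embedding matrix (n_nodes x embedding_dim) for one graph."""
    if graph.scope != model.config.scope:
        raise ValueError(
            f"graph scope {graph.scope!r} does not match model scope {model.config.scope!r}"
        )
    if graph.node_features.shape[1] != model.config.input_dim:
        raise ValueError(
            f"node feature width {graph.node_features.shape[1]} != input_dim {model.config.input_dim}"
        )
    return _forward(_PreparedGraph(graph), model)


def global_mean_pool(node_matrix: np.ndarray) -> np.ndarray:
    """Column-wise mean of the node embedding matrix."""
    node_matrix = np.asarray(node_matrix, dtype=float)
    if node_matrix.ndim != 2 or node_matrix.shape[0] == 0:
        raise ValueError("global_mean_pool requires a non-empty 2-D matrix")
    return node_matrix.mean(axis=0)


def inner_product_decode(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """Edge probability sigmoid(z_i . z_j); symmetric in its arguments."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape:
        raise ValueError("embedding dimension mismatch")
    return float(_sigmoid(z_i @ z_j))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _decode_pairs(z: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.zeros(0)
    return _sigmoid(np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]]))


def negative_sample(graph, n_samples: int | None = None, seed: int = 0) -> np.ndarray:
    """Uniform sample (without replacement) of non-adjacent node pairs.

    Defaults to as many samples as the graph has edges; capped at the number
    of available non-edges.
    """
    prep = graph if isinstance(graph, _PreparedGraph) else _PreparedGraph(graph)
    non_edges = prep.non_edges()
    if len(non_edges) == 0:
        raise SamplingError("graph is complete; no negative pairs available")
    if n_samples is None:
        n_samples = max(1, len(prep.edges))
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_samples = min(n_samples, len(non_edges))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(non_edges), size=n_samples, replace=False)
    return non_edges[idx]


def reconstruction_loss(pos_probs, neg_probs) -> float:
    """mean(-log p_pos) + mean(-log(1 - p_neg)), probabilities clamped at 1e-15."""
    pos = np.clip(np.asarray(pos_probs, dtype=float), _PROB_CLAMP, 1 - _PROB_CLAMP)
    neg = np.clip(np.asarray(neg_probs, dtype=float), _PROB_CLAMP, 1 - _PROB_CLAMP)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both probability sequences must be non-empty")
    return float(np.mean(-np.log(pos)) + np.mean(-np.log(1.0 - neg)))


def _loss_and_grad(z: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """BCE loss over positive and negative pairs plus its gradient w.r.t. z."""
    dz = np.zeros_like(z)
    s_pos = np.einsum("ij,ij->i", z[pos[:, 0]], z[pos[:, 1]])
    p_pos = _sigmoid(s_pos)
    s_neg = np.einsum("ij,ij->i", z[neg[:, 0]], z[neg[:, 1]])
    p_neg = _sigmoid(s_neg)
    loss = reconstruction_loss(p_pos, p_neg)
    ds_pos = (p_pos - 1.0) / len(pos)
    np.add.at(dz, pos[:, 0], ds_pos[:, None] * z[pos[:, 1]])
    np.add.at(dz, pos[:, 1], ds_pos[:, None] * z[pos[:, 0]])
    ds_neg = p_neg / len(neg)
    np.add.at(dz, neg[:, 0], ds_neg[:, None] * z[neg[:, 1]])
    np.add.at(dz, neg[:, 1], ds_neg[:, None] * z[neg[:, 0]])
    return loss, dz


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _split_graphs(n: int, split, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    return order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]


def _edge_accuracy(z: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> tuple[int, int]:
    p_pos = _decode_pairs(z, pos)
    p_neg = _decode_pairs(z, neg)
    correct = int((p_pos > 0.5).sum() + (p_neg <= 0.5).sum())
    return correct, len(pos) + len(neg)


def train_gae(
    graphs: list[ProteinGraph],
    enc_config: EncoderConfig,
    train_config: TrainConfig | None = None,
) -> tuple[GAEModel, TrainHistory]:
    """Train a graph autoencoder on a set of graphs.

    Structures are split 70/20/10 into train/validation/test. Each epoch
    iterates mini-batches of whole graphs, resampling training negatives;
    validation and test negatives are fixed once so the early-stopping signal
    is stable. The returned parameters are the best-validation-epoch snapshot.
    """
    if train_config is None:
        train_config = TrainConfig()
    if len(graphs) < 10:
        raise ValueError("training requires at least 10 graphs for a 70/20/10 split")
    rng = np.random.default_rng(train_config.seed)

    preps = [_PreparedGraph(g) for g in graphs]
    tr_idx, va_idx, te_idx = _split_graphs(len(graphs), train_config.split, rng)

    # fixed negatives for validation and test
    fixed_neg = {}
    for i in np.concatenate([va_idx, te_idx]):
        fixed_neg[int(i)] = negative_sample(
            preps[i], n_samples=max(1, len(preps[i].edges)),
            seed=int(rng.integers(2 ** 31)),
        )

    model = init_model(enc_config, seed=int(rng.integers(2 ** 31)))
    opt = _Adam(model.params, train_config.learning_rate)
    stopper = EarlyStopper(train_config.patience)
    best_params = model.copy_params()

    losses, accs = [], []
    stopped_epoch = train_config.max_epochs
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch = tr_idx[order[start:start + train_config.batch_size]]
            grads_sum = None
            for gi in batch:
                prep = preps[gi]
                if len(prep.edges) == 0:
                    continue
                z, caches = _forward(prep, model, want_cache=True)
                neg = negative_sample(
                    prep, n_samples=len(prep.edges), seed=int(rng.integers(2 ** 31))
                )
                loss, dz = _loss_and_grad(z, prep.edges, neg)
                grads = _backward(prep, model, caches, dz)
                epoch_losses.append(loss)
                if grads_sum is None:
                    grads_sum = grads
                else:
                    for k in grads_sum:
                        grads_sum[k] += grads[k]
            if grads_sum is not None:
                for k in grads_sum:
                    grads_sum[k] /= len(batch)
                opt.step(model.params, grads_sum)
        losses.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))

        correct = total = 0
        for gi in va_idx:
            prep = preps[gi]
            if len(prep.edges) == 0:
                continue
            z = _forward(prep, model)
            c, t = _edge_accuracy(z, prep.edges, fixed_neg[int(gi)])
            correct += c
            total += t
        acc = correct / total if total else 0.0
        accs.append(acc)
        if acc > stopper.best:
            best_params = model.copy_params()
        if stopper.update(epoch, acc):
            stopped_epoch = epoch
            break
    else:
        stopped_epoch = train_config.max_epochs

    model.params = best_params
    labels, scores = [], []
    for gi in te_idx:
        prep = preps[gi]
        if len(prep.edges) == 0:
            continue
        z = _forward(prep, model)
        p_pos = _decode_pairs(z, prep.edges)
        p_neg = _decode_pairs(z, fixed_neg[int(gi)])
        scores.extend(p_pos)
        scores.extend(p_neg)
        labels.extend([1] * len(p_pos) + [0] * len(p_neg))
    test_auc = auroc_rank(labels, scores) if labels else float("nan")
    test_ap = average_precision(labels, scores) if labels else float("nan")

    history = TrainHistory(
        train_loss=losses,
        val_accuracy=accs,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopped_epoch,
        test_auc=test_auc,
        test_ap=test_ap,
    )
    return model, history


def evaluate_gae(model: GAEModel, test_graphs: list[ProteinGraph], seed: int = 0) -> tuple[float, float]:
    """Edge-reconstruction AUC and average precision pooled over test graphs."""
    if not test_graphs:
        raise ValueError("test set is empty")
    rng = np.random.default_rng(seed)
    labels, scores = [], []
    for g in test_graphs:
        prep = _PreparedGraph(g)
        if len(prep.edges) == 0:
            continue
        z = _forward(prep, model)
        neg = negative_sample(prep, n_samples=len(prep.edges), seed=int(rng.integers(2 ** 31)))
        scores.extend(_decode_pairs(z, prep.edges))
        scores.extend(_decode_pairs(z, neg))
        labels.extend([1] * len(prep.edges) + [0] * len(neg))
    return auroc_rank(labels, scores), average_precision(labels, scores)


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: GAEModel, path) -> None:
    """Single-file archive: named parameter arrays + JSON encoder config."""
    buf = io.BytesIO()
    np.savez(buf, **model.params)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("config.json", json.dumps(asdict(model.config)))


def load_model(path) -> GAEModel:
    with zipfile.ZipFile(path) as zf:
        cfg = EncoderConfig(**json.loads(zf.read("config.json")))
        with zf.open("params.npz") as fh:
            npz = np.load(io.BytesIO(fh.read()))
            params = {k: npz[k] for k in npz.files}
    return GAEModel(config=cfg, params=params)
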