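"""Minimal numpy neural-network core for the scoring model.

Implements exactly the pieces the scoring network needs -- relational
graph-convolution layers, mean pooling, a feed-forward decoder and an Adam
optimizer -- with hand-written reverse-mode gradients (verified against
finite differences in the test suite).  The rGCN update for node ``i`` at
layer ``l`` is

    h_i^{l+1} = act( W_0 h_i^l + sum_r sum_{j in N_r(i)} (1/c_ir) W_r h_j^l + b )

with ``c_ir = |N_r(i)|``: one weight matrix per relation plus one for the
self loop, and per-relation mean normalization.  Nodes without
``r``-neighbours contribute no ``r`` term.  A plain GCN is the single
relation (``r = 1``) special case used for the ligand encoder.

Graphs are presented to the network as :class:`GraphTensor` objects: a
node-feature matrix plus one row-normalized adjacency matrix per relation,
where entry ``(i, j)`` carries ``1/c_ir`` for each edge ``j -> i`` with
relation ``r`` (messages flow along edge direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GraphTensor",
    "pocket_tensor",
    "ligand_tensor",
    "RGCNEncoder",
    "MLP",
    "Adam",
    "relu",
]

LIGAND_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "other")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class GraphTensor:
    """A graph ready for the network: features + per-relation adjacency."""

    graph_id: str
    node_order: list
    features: np.ndarray  # (n, d_in)
    adj: list[np.ndarray]  # one (n, n) row-normalized matrix per relation

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def n_relations(self) -> int:
        return len(self.adj)


def pocket_tensor(g, use_lm: bool | None = None) -> GraphTensor:
    """Build the :class:`GraphTensor` of a pocket graph.

    ``use_lm=None`` uses language-model features whenever present; when
    absent the input is the nucleotide one-hot alone (smaller input dim,
    not zero-padding).
    """
    order = g.node_ids
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    if use_lm is None:
        use_lm = g.lm_dim > 0
    feats = []
    for node in order:
        x = g.node_features(node)
        feats.append(x if use_lm else x[:5])
    X = np.asarray(feats, dtype=float)
    rel_index = {r: k for k, r in enumerate(g.relation_vocab)}
    counts = np.zeros((len(rel_index), n))
    adj = [np.zeros((n, n)) for _ in rel_index]
    for u, v, lab in g.edges():
        k = rel_index[lab]
        adj[k][index[v], index[u]] = 1.0
        counts[k, index[v]] += 1
    for k in range(len(adj)):
        nz = counts[k] > 0
        adj[k][nz] /= counts[k][nz, None]
    return GraphTensor(g.pocket_id, order, X, adj)


def ligand_tensor(record) -> GraphTensor:
    """Build the single-relation :class:`GraphTensor` of a molecular graph.

    Node features: one-hot element (10 classes), aromatic flag, formal
    charge.  Bonds are treated as one undirected relation.
    """
    mg = record.mol_graph
    order = sorted(mg.nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    X = np.zeros((n, len(LIGAND_ELEMENTS) + 2))
    for node in order:
        d = mg.nodes[node]
        el = d["element"]
        j = (
            LIGAND_ELEMENTS.index(el)
            if el in LIGAND_ELEMENTS
            else LIGAND_ELEMENTS.index("other")
        )
        i = index[node]
        X[i, j] = 1.0
        X[i, -2] = 1.0 if d["aromatic"] else 0.0
        X[i, -1] = float(d["formal_charge"])
    A = np.zeros((n, n))
    for u, v in mg.edges:
        A[index[u], index[v]] = 1.0
        A[index[v], index[u]] = 1.0
    deg = A.sum(axis=1)
    nz = deg > 0
    A[nz] /= deg[nz, None]
    return GraphTensor(record.ligand_id, order, X, [A])


def ligand_input_dim() -> int:
    return len(LIGAND_ELEMENTS) + 2


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class RGCNEncoder:
    """Stack of rGCN layers with mean pooling into a graph-level embedding."""

    def __init__(
        self,
        n_relations: int,
        in_dim: int,
        hidden_dims: list[int],
        seed: int = 0,
        activation: str = "relu",
    ) -> None:
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation: {activation!r}")
        self.n_relations = n_relations
        self.in_dim = in_dim
        self.hidden_dims = list(hidden_dims)
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        dims = [in_dim] + self.hidden_dims
        for l, (d_in, d_out) in enumerate(zip(dims, dims[1:])):
            self.params[f"l{l}.W0"] = _glorot(rng, d_out, d_in)
            self.params[f"l{l}.Wr"] = np.stack(
                [_glorot(rng, d_out, d_in) for _ in range(n_relations)]
            )
            self.params[f"l{l}.b"] = np.zeros(d_out)

    @property
    def out_dim(self) -> int:
        return self.hidden_dims[-1]

    @property
    def n_layers(self) -> int:
        return len(self.hidden_dims)

    def layer_forward(self, H: np.ndarray, gt: GraphTensor, l: int) -> np.ndarray:
        """One rGCN layer (activation included)."""
        if gt.n_relations != self.n_relations:
            raise ValueError(
                f"graph has {gt.n_relations} relations, encoder expects {self.n_relations}"
            )
        W0 = self.params[f"l{l}.W0"]
        Wr = self.params[f"l{l}.Wr"]
        if H.shape[1] != W0.shape[1]:
            raise ValueError(f"feature dim {H.shape[1]} != layer in_dim {W0.shape[1]}")
        Z = H @ W0.T + self.params[f"l{l}.b"]
        for r in range(self.n_relations):
            A = gt.adj[r]
            if A.any():
                Z += (A @ H) @ Wr[r].T
        return relu(Z) if self.activation == "relu" else Z

    def node_embeddings(self, gt: GraphTensor) -> np.ndarray:
        H = gt.features
        for l in range(self.n_layers):
            H = self.layer_forward(H, gt, l)
        return H

    def embed(self, gt: GraphTensor, cache: list | None = None) -> np.ndarray:
        """Graph-level embedding: mean pooling over final node embeddings."""
        if gt.n_nodes == 0:
            raise ValueError("cannot embed an empty graph")
        H = gt.features
        for l in range(self.n_layers):
            H_in = H
            W0 = self.params[f"l{l}.W0"]
            Wr = self.params[f"l{l}.Wr"]
            Z = H_in @ W0.T + self.params[f"l{l}.b"]
            msgs = []
            for r in range(self.n_relations):
                M = gt.adj[r] @ H_in
                msgs.append(M)
                Z += M @ Wr[r].T
            H = relu(Z) if self.activation == "relu" else Z
            if cache is not None:
                cache.append((H_in, Z, msgs))
        return H.mean(axis=0)

    def backward(
        self,
        gt: GraphTensor,
        cache: list,
        d_emb: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        """Accumulate parameter gradients for one graph into ``grads``."""
        n = gt.n_nodes
        dH = np.repeat(d_emb[None, :] / n, n, axis=0)
        for l in range(self.n_layers - 1, -1, -1):
            H_in, Z, msgs = cache[l]
            dZ = dH * (Z > 0) if self.activation == "relu" else dH
            W0 = self.params[f"l{l}.W0"]
            Wr = self.params[f"l{l}.Wr"]
            grads[f"l{l}.W0"] += dZ.T @ H_in
            grads[f"l{l}.b"] += dZ.sum(axis=0)
            dH = dZ @ W0
            for r in range(self.n_relations):
                grads[f"l{l}.Wr"][r] += dZ.T @ msgs[r]
                A = gt.adj[r]
                if A.any():
                    dH += A.T @ (dZ @ Wr[r])
        # gradient w.r.t. input features is discarded (inputs are data)


class MLP:
    """Two-layer feed-forward decoder producing a real score per row."""

    def __init__(self, in_dim: int, hidden_dim: int, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        self.hidden_dim = hidden_dim
        self.params = {
            "V1": _glorot(rng, hidden_dim, in_dim),
            "c1": np.zeros(hidden_dim),
            "V2": _glorot(rng, 1, hidden_dim),
            "c2": np.zeros(1),
        }

    def forward(self, U: np.ndarray, cache: list | None = None) -> np.ndarray:
        if U.shape[1] != self.in_dim:
            raise ValueError(f"decoder input dim {U.shape[1]} != expected {self.in_dim}")
        Z1 = U @ self.params["V1"].T + self.params["c1"]
        H1 = relu(Z1)
        out = (H1 @ self.params["V2"].T + self.params["c2"]).ravel()
        if cache is not None:
            cache.append((U, Z1, H1))
        return out

    def backward(
        self, cache: tuple, d_out: np.ndarray, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        U, Z1, H1 = cache
        d_out = d_out.reshape(-1, 1)
        grads["V2"] += d_out.T @ H1
        grads["c2"] += d_out.sum(axis=0)
        dH1 = d_out @ self.params["V2"]
        dZ1 = dH1 * (Z1 > 0)
        grads["V1"] += dZ1.T @ U
        grads["c1"] += dZ1.sum(axis=0)
        return dZ1 @ self.params["V1"]


def zero_grads_like(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-2,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
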