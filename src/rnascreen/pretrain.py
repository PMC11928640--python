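"""Self-supervised pocket-encoder pretraining.

The encoder is pretrained so that the dot product of two subgraph
embeddings approximates a structural similarity kernel between the
subgraphs.  Subgraphs are hop-neighbourhoods of whole RNA graphs
(default radius 2).  The kernel decomposes each subgraph into per-node
rooted graphlets (radius-1 induced subgraphs), computes a label-aware
graph edit distance between every graphlet pair, solves the resulting
(rectangular, indel-padded) assignment problem with the Hungarian
algorithm, and maps the optimal matching cost onto [0, 1].

The training objective is the metric-learning loss

    L = ( <phi(G1), phi(G2)> - k(G1, G2) )^2 .
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .nn import RGCNEncoder, pocket_tensor, zero_grads_like, Adam
from .pockets import PocketGraph

__all__ = [
    "SimilarityKernel",
    "RootedSubgraph",
    "PretrainBatch",
    "build_pretrain_batch",
    "extract_neighborhoods",
    "graphlet_kernel",
    "metric_loss",
    "pretrain_encoder",
    "GraphletKernelPretrainer",
]


@dataclass
class SimilarityKernel:
    """Configuration of the graphlet-matching similarity kernel.

    Costs: node/edge substitution cost applies on label mismatch, indels
    cost ``indel_cost`` each.  ``normalization="unit-interval"`` divides
    the optimal matching cost by the full delete-everything cost, so
    ``k(G, G) = 1`` and ``k`` is within [0, 1].
    """

    neighborhood_radius: int = 2
    graphlet_radius: int = 1
    node_subst_cost: float = 1.0
    edge_subst_cost: float = 1.0
    indel_cost: float = 1.0
    normalization: str = "unit-interval"

    def __post_init__(self) -> None:
        if min(self.node_subst_cost, self.edge_subst_cost, self.indel_cost) < 0:
            raise ValueError("edit costs must be >= 0")
        if self.normalization not in ("none", "unit-interval"):
            raise ValueError(f"unknown normalization: {self.normalization!r}")


@dataclass
class RootedSubgraph:
    root: str
    graph: nx.DiGraph  # node attr 'nt', edge attr 'label'
    relation_vocab: tuple


def _rooted_ball(g: PocketGraph, root: str, radius: int) -> RootedSubgraph:
    und = g.undirected()
    nodes = {root}
    frontier = {root}
    for _ in range(radius):
        nxt = set()
        for n in frontier:
            nxt.update(und.neighbors(n))
        nxt -= nodes
        nodes |= nxt
        frontier = nxt
    return RootedSubgraph(root, g.graph.subgraph(nodes).copy(), g.relation_vocab)


def extract_neighborhoods(whole: PocketGraph, radius: int = 2) -> list[RootedSubgraph]:
    """One rooted induced subgraph per node: all nodes within ``radius`` hops."""
    if whole.n_nodes == 0:
        raise ValueError("cannot extract neighborhoods of an empty graph")
    return [_rooted_ball(whole, n, radius) for n in whole.node_ids]


def _graphlet_cost(g: nx.DiGraph, cfg: SimilarityKernel) -> float:
    """Cost of deleting (or inserting) an entire graphlet."""
    return cfg.indel_cost * (g.number_of_nodes() + g.number_of_edges())


_GED_CACHE: dict[tuple, float] = {}


def _graphlet_signature(sg: RootedSubgraph) -> str:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # nx 3.5 WL-hash change note
        h = nx.weisfeiler_lehman_graph_hash(
            sg.graph, node_attr="nt", edge_attr="label", iterations=3
        )
    return f"{h}|{sg.graph.nodes[sg.root]['nt']}|{sg.graph.degree(sg.root)}"


def _graphlet_distance(a: RootedSubgraph, b: RootedSubgraph, cfg: SimilarityKernel) -> float:
    """Exact label-aware graph edit distance between two small rooted graphlets."""
    key_a, key_b = _graphlet_signature(a), _graphlet_signature(b)
    cost_key = (min(key_a, key_b), max(key_a, key_b), cfg.node_subst_cost, cfg.edge_subst_cost, cfg.indel_cost)
    if cost_key in _GED_CACHE:
        return _GED_CACHE[cost_key]

    def node_subst(x, y):
        return 0.0 if x["nt"] == y["nt"] else cfg.node_subst_cost

    def edge_subst(x, y):
        return 0.0 if x["label"] == y["label"] else cfg.edge_subst_cost

    dist = nx.graph_edit_distance(
        a.graph,
        b.graph,
        node_subst_cost=node_subst,
        node_del_cost=lambda x: cfg.indel_cost,
        node_ins_cost=lambda x: cfg.indel_cost,
        edge_subst_cost=edge_subst,
        edge_del_cost=lambda x: cfg.indel_cost,
        edge_ins_cost=lambda x: cfg.indel_cost,
        roots=(a.root, b.root),
    )
    _GED_CACHE[cost_key] = float(dist)
    return float(dist)


def graphlet_kernel(
    g1: RootedSubgraph | PocketGraph,
    g2: RootedSubgraph | PocketGraph,
    cfg: SimilarityKernel | None = None,
) -> float:
    """Graphlet-matching similarity between two RNA subgraphs.

    Each graph is decomposed into per-node rooted graphlets of radius
    ``cfg.graphlet_radius``; the pairwise graphlet edit-distance matrix is
    padded to square with full-deletion costs and the optimal assignment is
    solved by the Hungarian algorithm.  Under unit-interval normalization
    the returned value is ``1 - cost / max_cost`` where ``max_cost`` is the
    delete-and-reinsert-everything cost, giving a symmetric similarity in
    [0, 1] that equals 1 on identically labelled isomorphic graphs.
    """
    cfg = cfg or SimilarityKernel()

    def as_pocket(g):
        if isinstance(g, RootedSubgraph):
            pg = PocketGraph("sub", g.relation_vocab)
            pg.graph = g.graph
            return pg
        return g

    p1, p2 = as_pocket(g1), as_pocket(g2)
    if p1.relation_vocab != p2.relation_vocab:
        raise ValueError("relation vocabulary mismatch between graphs")
    gl1 = [_rooted_ball(p1, n, cfg.graphlet_radius) for n in p1.node_ids]
    gl2 = [_rooted_ball(p2, n, cfg.graphlet_radius) for n in p2.node_ids]
    n1, n2 = len(gl1), len(gl2)
    size = max(n1, n2)
    costs1 = [_graphlet_cost(g.graph, cfg) for g in gl1]
    costs2 = [_graphlet_cost(g.graph, cfg) for g in gl2]
    C = np.zeros((size, size))
    for i in range(size):
        for j in range(size):
            if i < n1 and j < n2:
                C[i, j] = _graphlet_distance(gl1[i], gl2[j], cfg)
            elif i < n1:
                C[i, j] = costs1[i]  # unmatched graphlet of g1 is deleted
            elif j < n2:
                C[i, j] = costs2[j]  # unmatched graphlet of g2 is inserted
    rows, cols = linear_sum_assignment(C)
    total = float(C[rows, cols].sum())
    if cfg.normalization == "none":
        return -total
    max_cost = float(sum(costs1) + sum(costs2))
    if max_cost == 0:
        return 1.0
    return 1.0 - total / max_cost


def metric_loss(e1: np.ndarray, e2: np.ndarray, target: float) -> float:
    """Squared error between the embedding dot product and the kernel value."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"embedding dim mismatch: {e1.shape} vs {e2.shape}")
    if not np.isfinite(target):
        raise ValueError("target kernel value must be finite")
    return float((float(e1 @ e2) - target) ** 2)


def sample_pretrain_pairs(
    subgraphs: list[RootedSubgraph],
    by_graph: list[list[int]],
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Uniform random root pairs; half drawn within the same whole RNA so
    overlapping, high-similarity neighbourhoods are well covered."""
    pairs = []
    for _ in range(n_pairs):
        if rng.random() < 0.5 and any(len(ix) > 1 for ix in by_graph):
            ix = by_graph[rng.integers(len(by_graph))]
            while len(ix) < 2:
                ix = by_graph[rng.integers(len(by_graph))]
            i, j = rng.choice(ix, size=2, replace=False)
        else:
            i, j = rng.choice(len(subgraphs), size=2, replace=False)
        pairs.append((int(i), int(j)))
    return pairs


@dataclass
class PretrainBatch:
    """Sampled subgraph pairs with their kernel targets."""

    subgraphs: list[RootedSubgraph]
    pairs: list[tuple[int, int]]
    kernel_values: np.ndarray
    relation_vocab: tuple

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel_values, dtype=float)
        if len(k) != len(self.pairs):
            raise ValueError("one kernel value per pair required")
        if ((k < -1e-9) | (k > 1 + 1e-9)).any():
            raise ValueError("kernel targets must lie in [0, 1]")


def build_pretrain_batch(
    corpus: list[PocketGraph],
    cfg: SimilarityKernel | None = None,
    n_pairs: int = 200,
    seed: int = 0,
) -> PretrainBatch:
    """Sample neighbourhood pairs from a corpus and compute kernel targets."""
    if not corpus:
        raise ValueError("pretraining corpus is empty")
    cfg = cfg or SimilarityKernel()
    rng = np.random.default_rng(seed)
    subgraphs: list[RootedSubgraph] = []
    by_graph: list[list[int]] = []
    for g in corpus:
        hoods = extract_neighborhoods(g, cfg.neighborhood_radius)
        by_graph.append(list(range(len(subgraphs), len(subgraphs) + len(hoods))))
        subgraphs.extend(hoods)
    pairs = sample_pretrain_pairs(subgraphs, by_graph, n_pairs, rng)
    targets = np.array([graphlet_kernel(subgraphs[i], subgraphs[j], cfg) for i, j in pairs])
    return PretrainBatch(subgraphs, pairs, targets, corpus[0].relation_vocab)


def pretrain_encoder(
    corpus: list[PocketGraph],
    encoder: RGCNEncoder | None = None,
    cfg: SimilarityKernel | None = None,
    epochs: int = 50,
    n_pairs: int = 200,
    learning_rate: float = 5e-3,
    seed: int = 0,
    use_lm: bool = False,
    batch: PretrainBatch | None = None,
) -> tuple[RGCNEncoder, pd.DataFrame]:
    """Pretrain a pocket encoder on kernel targets from a corpus of RNA graphs.

    Samples ``n_pairs`` neighbourhood pairs once (or reuses a precomputed
    ``batch``), computes their kernel values, then minimizes the metric
    loss by full-batch Adam for ``epochs`` epochs.  Returns the updated
    encoder (usable as a supervised initialization) and a log with one row
    per epoch (epoch, mean_loss).
    """
    if not corpus:
        raise ValueError("pretraining corpus is empty")
    cfg = cfg or SimilarityKernel()
    vocab = corpus[0].relation_vocab
    if batch is None:
        batch = build_pretrain_batch(corpus, cfg, n_pairs=n_pairs, seed=seed)
    subgraphs, pairs, targets = batch.subgraphs, batch.pairs, batch.kernel_values
    if encoder is None:
        encoder = RGCNEncoder(len(vocab), 5, [64, 64, 64], seed=seed)
    used = sorted({i for p in pairs for i in p})
    tensors = {}
    for i in used:
        sg = subgraphs[i]
        pg = PocketGraph(f"sub{i}", vocab)
        pg.graph = sg.graph
        tensors[i] = pocket_tensor(pg, use_lm=use_lm)

    opt = Adam(encoder.params, lr=learning_rate)
    log = []
    for epoch in range(epochs):
        grads = zero_grads_like(encoder.params)
        caches = {}
        embs = {}
        for i in used:
            cache: list = []
            embs[i] = encoder.embed(tensors[i], cache)
            caches[i] = cache
        d_embs = {i: np.zeros_like(embs[i]) for i in used}
        losses = []
        for (i, j), k in zip(pairs, targets):
            delta = float(embs[i] @ embs[j]) - k
            losses.append(delta**2)
            d_embs[i] += 2 * delta * embs[j]
            d_embs[j] += 2 * delta * embs[i]
        for i in used:
            encoder.backward(tensors[i], caches[i], d_embs[i], grads)
        for k_ in grads:
            grads[k_] /= len(pairs)
        opt.step(encoder.params, grads)
        log.append({"epoch": epoch, "mean_loss": float(np.mean(losses))})
    return encoder, pd.DataFrame(log)


class GraphletKernelPretrainer:
    """Scikit-learn style wrapper around :func:`pretrain_encoder`.

    After ``fit(corpus)`` the pretrained encoder is available as
    ``encoder_`` (pass it to a supervised scorer as initialization) and
    the per-epoch loss log as ``log_``.
    """

    def __init__(
        self,
        neighborhood_radius: int = 2,
        graphlet_radius: int = 1,
        n_pairs: int = 200,
        epochs: int = 50,
        learning_rate: float = 5e-3,
        hidden_dims: tuple = (64, 64, 64),
        random_state: int = 0,
    ) -> None:
        self.neighborhood_radius = neighborhood_radius
        self.graphlet_radius = graphlet_radius
        self.n_pairs = n_pairs
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden_dims = hidden_dims
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "neighborhood_radius", "graphlet_radius", "n_pairs", "epochs",
                "learning_rate", "hidden_dims", "random_state",
            )
        }

    def set_params(self, **params) -> "GraphletKernelPretrainer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter: {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, corpus: list[PocketGraph], y=None) -> "GraphletKernelPretrainer":
        cfg = SimilarityKernel(
            neighborhood_radius=self.neighborhood_radius,
            graphlet_radius=self.graphlet_radius,
        )
        encoder = RGCNEncoder(
            len(corpus[0].relation_vocab), 5, list(self.hidden_dims),
            seed=self.random_state,
        )
        self.encoder_, self.log_ = pretrain_encoder(
            corpus,
            encoder=encoder,
            cfg=cfg,
            epochs=self.epochs,
            n_pairs=self.n_pairs,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )
        return self

    def transform(self, graphs: list[PocketGraph]) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("pretrainer is not fitted; call fit first")
        return np.array([self.encoder_.embed(pocket_tensor(g, use_lm=False)) for g in graphs])
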