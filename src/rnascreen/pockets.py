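"""Directed 2.5D RNA binding-site graphs.

A binding site is modelled as a directed, node- and edge-labelled graph.
Nodes are nucleotides carrying a one-hot nucleotide type and, optionally, a
fixed-length language-model feature vector.  Edges carry a relation label
from a closed vocabulary: the two backbone relations ``B53`` (5'->3') and
``B35`` (3'->5'), plus the twelve Leontis-Westhof base-pair families
(cis/trans x Watson-Crick/Hoogsteen/Sugar edge combinations).  Every
interaction is stored as a pair of directed edges; asymmetric families swap
their edge sublabels on the reversed edge (``cWH`` from i to j is paired
with ``cHW`` from j to i), which disambiguates sequence orientation and
asymmetric non-canonical pairs.

The module also provides binding-site extraction from 3D structures (all
RNA residues with an atom within a distance cutoff of the ligand, with
size and protein-contamination filters), breadth-first context expansion,
and a JSON serialization used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BACKBONE_RELATIONS",
    "LW_SYMMETRIC",
    "LW_ASYMMETRIC",
    "DEFAULT_RELATION_VOCAB",
    "NT_TYPES",
    "reverse_relation",
    "Nucleotide",
    "PocketGraph",
    "PocketRejected",
    "extract_binding_site",
    "expand_context",
    "read_pocket_json",
    "write_pocket_json",
]

BACKBONE_RELATIONS = ("B53", "B35")

#: Leontis-Westhof families whose two partners use the same base edge.
LW_SYMMETRIC = ("cWW", "tWW", "cHH", "tHH", "cSS", "tSS")

#: Families pairing two different base edges; stored once per direction.
LW_ASYMMETRIC = ("cWH", "tWH", "cWS", "tWS", "cHS", "tHS")


def reverse_relation(label: str) -> str:
    """Relation label carried by the reversed edge of an interaction."""
    if label == "B53":
        return "B35"
    if label == "B35":
        return "B53"
    if len(label) == 3 and label[0] in "ct":
        return label[0] + label[2] + label[1]
    raise ValueError(f"unknown relation label: {label!r}")


def _directional_variants() -> tuple[str, ...]:
    out = list(LW_SYMMETRIC)
    for fam in LW_ASYMMETRIC:
        out.append(fam)
        out.append(reverse_relation(fam))
    return tuple(out)


#: 2 backbone relations + 12 LW families with directional variants (20 labels).
DEFAULT_RELATION_VOCAB: tuple[str, ...] = BACKBONE_RELATIONS + _directional_variants()

NT_TYPES = ("A", "C", "G", "U", "other")


def nt_one_hot(nt_type: str) -> np.ndarray:
    vec = np.zeros(len(NT_TYPES))
    idx = NT_TYPES.index(nt_type) if nt_type in NT_TYPES else NT_TYPES.index("other")
    vec[idx] = 1.0
    return vec


@dataclass
class Nucleotide:
    """A pocket-graph node: one residue, keyed ``chain.position[.insertion]``."""

    node_id: str
    nt_type: str
    is_core: bool = True
    lm_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nt_type not in NT_TYPES:
            self.nt_type = "other"
        if self.lm_features is not None:
            self.lm_features = np.asarray(self.lm_features, dtype=float)

    @property
    def one_hot(self) -> np.ndarray:
        return nt_one_hot(self.nt_type)


class PocketGraphError(ValueError):
    pass


class PocketGraph:
    """Directed node/edge-labelled graph of an RNA binding site with context.

    Wraps a :class:`networkx.DiGraph`.  ``core_ids`` marks the original
    pocket residues (before context expansion); the relation vocabulary is
    fixed at construction and recorded in the serialization header so model
    weights and graphs stay consistent.
    """

    def __init__(
        self,
        pocket_id: str,
        relation_vocab: Sequence[str] = DEFAULT_RELATION_VOCAB,
    ) -> None:
        self.pocket_id = pocket_id
        self.relation_vocab = tuple(relation_vocab)
        self.graph = nx.DiGraph()

    # -- construction -----------------------------------------------------

    def add_nucleotide(self, nt: Nucleotide) -> None:
        if nt.node_id in self.graph:
            raise PocketGraphError(f"duplicate node_id: {nt.node_id!r}")
        self.graph.add_node(
            nt.node_id, nt=nt.nt_type, is_core=bool(nt.is_core), lm=nt.lm_features
        )

    def add_node(
        self,
        node_id: str,
        nt_type: str,
        is_core: bool = True,
        lm_features: np.ndarray | None = None,
    ) -> None:
        self.add_nucleotide(Nucleotide(node_id, nt_type, is_core, lm_features))

    def add_edge(self, src: str, dst: str, label: str) -> None:
        """Add a single directed edge (the caller supplies the reverse)."""
        if label not in self.relation_vocab:
            raise PocketGraphError(f"unknown relation label: {label!r}")
        for n in (src, dst):
            if n not in self.graph:
                raise PocketGraphError(f"edge endpoint not in graph: {n!r}")
        self.graph.add_edge(src, dst, label=label)

    def add_interaction(self, src: str, dst: str, label: str) -> None:
        """Add an interaction as reciprocal directed edges with swapped labels."""
        self.add_edge(src, dst, label)
        self.add_edge(dst, src, reverse_relation(label))

    # -- views ------------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def core_ids(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["is_core"]}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nucleotide(self, node_id: str) -> Nucleotide:
        d = self.graph.nodes[node_id]
        return Nucleotide(node_id, d["nt"], d["is_core"], d.get("lm"))

    def edges(self) -> Iterable[tuple[str, str, str]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["label"]

    @property
    def lm_dim(self) -> int:
        """Language-model feature length, 0 when features are absent."""
        for _, d in self.graph.nodes(data=True):
            lm = d.get("lm")
            return 0 if lm is None else int(len(lm))
        return 0

    def node_features(self, node_id: str) -> np.ndarray:
        d = self.graph.nodes[node_id]
        one_hot = nt_one_hot(d["nt"])
        lm = d.get("lm")
        if lm is None:
            return one_hot
        return np.concatenate([one_hot, np.asarray(lm, dtype=float)])

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=True)

    def subgraph(self, node_ids: Iterable[str], pocket_id: str | None = None) -> "PocketGraph":
        """Induced subgraph on ``node_ids``, preserving labels and flags."""
        keep = set(node_ids)
        missing = keep - set(self.graph.nodes)
        if missing:
            raise PocketGraphError(f"nodes not in graph: {sorted(missing)}")
        out = PocketGraph(pocket_id or self.pocket_id, self.relation_vocab)
        for n in sorted(keep):
            out.add_nucleotide(self.nucleotide(n))
        for u, v, lab in self.edges():
            if u in keep and v in keep:
                out.graph.add_edge(u, v, label=lab)
        return out

    def set_core(self, core_ids: Iterable[str]) -> None:
        core = set(core_ids)
        missing = core - set(self.graph.nodes)
        if missing:
            raise PocketGraphError(f"core nodes not in graph: {sorted(missing)}")
        for n in self.graph.nodes:
            self.graph.nodes[n]["is_core"] = n in core

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Check structural invariants; returns a list of warnings.

        Hard violations (label vocabulary, edge reciprocity, inconsistent
        feature lengths, branching backbone) raise; soft issues (weak
        disconnection) are returned as warnings so callers may flag pockets
        without discarding them.
        """
        warnings: list[str] = []
        lm_dims = set()
        for n, d in self.graph.nodes(data=True):
            lm = d.get("lm")
            lm_dims.add(None if lm is None else len(lm))
        if len(lm_dims) > 1:
            raise PocketGraphError(
                "lm_features must be present with one length on all nodes or absent everywhere"
            )
        for u, v, d in self.graph.edges(data=True):
            lab = d["label"]
            if lab not in self.relation_vocab:
                raise PocketGraphError(f"unknown relation label: {lab!r}")
            rev = reverse_relation(lab)
            if not self.graph.has_edge(v, u) or self.graph.edges[v, u]["label"] != rev:
                raise PocketGraphError(
                    f"missing reciprocal edge {v}->{u} [{rev}] for {u}->{v} [{lab}]"
                )
        # backbone forms a simple path within each chain
        out_53: dict[str, int] = {}
        in_53: dict[str, int] = {}
        for u, v, d in self.graph.edges(data=True):
            if d["label"] == "B53":
                out_53[u] = out_53.get(u, 0) + 1
                in_53[v] = in_53.get(v, 0) + 1
        bad = [n for n, c in out_53.items() if c > 1] + [n for n, c in in_53.items() if c > 1]
        if bad:
            raise PocketGraphError(f"backbone branches at nodes: {sorted(set(bad))}")
        bb = nx.DiGraph((u, v) for u, v, d in self.graph.edges(data=True) if d["label"] == "B53")
        if bb.number_of_edges() and not nx.is_directed_acyclic_graph(bb):
            raise PocketGraphError("backbone contains a cycle")
        if self.n_nodes and not nx.is_weakly_connected(self.graph):
            warnings.append("graph is not weakly connected")
        return warnings

    # -- equality (used by round-trip tests) -------------------------------

    def structurally_equal(self, other: "PocketGraph") -> bool:
        if self.pocket_id != other.pocket_id:
            return False
        if self.relation_vocab != other.relation_vocab:
            return False
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            a, b = self.graph.nodes[n], other.graph.nodes[n]
            if a["nt"] != b["nt"] or a["is_core"] != b["is_core"]:
                return False
            la, lb = a.get("lm"), b.get("lm")
            if (la is None) != (lb is None):
                return False
            if la is not None and not np.allclose(la, lb):
                return False
        return set(self.edges()) == set(other.edges())


# ---------------------------------------------------------------------------
# JSON serialization


def write_pocket_json(g: PocketGraph, path) -> None:
    """Write a pocket to the package's JSON dialect (UTF-8, stable key order)."""
    nodes = []
    for n in g.node_ids:
        d = g.graph.nodes[n]
        rec: dict = {"id": n, "nt": d["nt"], "is_core": bool(d["is_core"])}
        lm = d.get("lm")
        if lm is not None:
            rec["lm_features"] = [float(x) for x in lm]
        nodes.append(rec)
    edges = [
        {"src": u, "dst": v, "label": lab}
        for u, v, lab in sorted(g.edges())
    ]
    payload = {
        "pocket_id": g.pocket_id,
        "relation_vocab": list(g.relation_vocab),
        "nodes": nodes,
        "edges": edges,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_pocket_json(path) -> PocketGraph:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    vocab = tuple(payload.get("relation_vocab", DEFAULT_RELATION_VOCAB))
    bad = sorted({e["label"] for e in payload["edges"]} - set(vocab))
    if bad:
        raise PocketGraphError(f"unknown relation labels in file: {bad}")
    g = PocketGraph(payload["pocket_id"], vocab)
    for rec in payload["nodes"]:
        g.add_node(
            rec["id"],
            rec["nt"],
            is_core=bool(rec.get("is_core", True)),
            lm_features=rec.get("lm_features"),
        )
    for e in payload["edges"]:
        g.add_edge(e["src"], e["dst"], e["label"])
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Context expansion


def expand_context(g: PocketGraph, whole: PocketGraph, depth: int = 4) -> PocketGraph:
    """Add context nodes around a binding site by breadth-first expansion.

    Returns the induced subgraph of ``whole`` on all nodes within ``depth``
    edge-direction-agnostic BFS hops of any core node of ``g``.  Core flags
    are preserved; added nodes are flagged ``is_core=False``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    core = g.core_ids or set(g.graph.nodes)
    missing = core - set(whole.graph.nodes)
    if missing:
        raise PocketGraphError(
            f"core node(s) absent from whole graph: {sorted(missing)}"
        )
    und = whole.undirected()
    reach = set(core)
    frontier = set(core)
    for _ in range(depth):
        nxt = set()
        for n in frontier:
            nxt.update(und.neighbors(n))
        nxt -= reach
        if not nxt:
            break
        reach |= nxt
        frontier = nxt
    out = whole.subgraph(reach, pocket_id=g.pocket_id)
    out.set_core(core)
    return out


# ---------------------------------------------------------------------------
# Binding-site extraction from 3D structures


class PocketRejected(Exception):
    """A candidate binding site failed the extraction filters.

    ``reason`` is a stable machine-readable code:
    ``"too few residues"`` or ``"protein-dominated"``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def _zone_residues(structure, ligand_id: str, cutoff: float):
    from scipy.spatial import cKDTree

    ligand = None
    for res in structure.residues:
        if res.key == ligand_id:
            ligand = res
            break
    if ligand is None:
        raise KeyError(f"ligand not found: {ligand_id!r}")
    if not any(r.kind == "rna" for r in structure.residues):
        raise ValueError("no RNA in structure")
    tree = cKDTree(np.asarray(ligand.coords, dtype=float))
    zone = []
    for res in structure.residues:
        if res.key == ligand_id or res.kind not in ("rna", "protein"):
            continue
        dmin = tree.query(np.asarray(res.coords, dtype=float), k=1)[0].min()
        if dmin <= cutoff:
            zone.append(res)
    return zone


def extract_binding_site(
    structure,
    ligand_id: str,
    cutoff: float = 10.0,
    min_rna_residues: int = 5,
    max_protein_fraction: float = 0.4,
    relation_vocab: Sequence[str] = DEFAULT_RELATION_VOCAB,
) -> PocketGraph:
    """Extract the binding site of ``ligand_id`` from a parsed structure.

    The pocket contains exactly the RNA residues with at least one atom
    within ``cutoff`` angstroms of any ligand atom.  Sites with fewer than
    ``min_rna_residues`` RNA residues, or where protein residues make up
    more than ``max_protein_fraction`` of all (RNA + protein) residues in
    the zone, are rejected with :class:`PocketRejected`.  Ions and waters
    never count toward the zone.

    ``structure`` follows the narrow adapter contract of
    :mod:`rnascreen.structures`: residues with ``key``, ``kind``
    (``rna``/``protein``/``ligand``/``ion``/``water``), ``name`` and atom
    ``coords``; backbone order given by chain + residue number; optional
    ``base_pairs`` annotations ``(key_i, key_j, lw_label)``.
    """
    zone = _zone_residues(structure, ligand_id, cutoff)
    rna = [r for r in zone if r.kind == "rna"]
    protein = [r for r in zone if r.kind == "protein"]
    if len(rna) < min_rna_residues:
        raise PocketRejected("too few residues", f"{len(rna)} RNA residues in zone")
    total = len(rna) + len(protein)
    if total and len(protein) / total > max_protein_fraction:
        raise PocketRejected(
            "protein-dominated",
            f"{len(protein)}/{total} residues from protein chains",
        )

    g = PocketGraph(f"{structure.structure_id}_{ligand_id}", relation_vocab)
    keep = {r.key for r in rna}
    for res in sorted(rna, key=lambda r: r.key):
        g.add_node(res.key, res.name if res.name in NT_TYPES else "other", is_core=True)
    # backbone: successive RNA residues of the same chain
    by_chain: dict[str, list] = {}
    for res in structure.residues:
        if res.kind == "rna":
            by_chain.setdefault(res.chain, []).append(res)
    for chain_residues in by_chain.values():
        chain_residues.sort(key=lambda r: (r.number, r.insertion))
        for a, b in zip(chain_residues, chain_residues[1:]):
            if a.key in keep and b.key in keep:
                g.add_interaction(a.key, b.key, "B53")
    for i, j, lab in getattr(structure, "base_pairs", []) or []:
        if i in keep and j in keep and not g.graph.has_edge(i, j):
            g.add_interaction(i, j, lab)
    g.validate()
    return g
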