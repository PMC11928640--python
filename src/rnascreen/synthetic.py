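"""Synthetic pockets, compound libraries and a planted docking oracle.

Everything downstream of structure parsing and docking can be exercised
without external data: this module generates RNA graphs with realistic
2.5D topology, drug-like-ish small molecules, and a planted bilinear
docking oracle whose ground truth the models can in principle recover.

Generated RNAs are hairpin-like: a backbone path over one or two chains,
a canonical cWW stem, and sprinkled non-canonical pairs drawn from the
twelve Leontis-Westhof families.  Each RNA carries a designated pocket
window whose *archetype* — non-canonical-pair-poor and A/U-rich
(``low``), or non-canonical-rich and G/C-rich (``high``) — is planted in
an otherwise neutral background.  The oracle scores a (pocket, ligand)
pair as

    score = -(w_p . desc(pocket)) * (w_l . desc(ligand)) + eps,
    eps ~ N(0, sigma^2) keyed per pair,

with pocket descriptors (edge-label fractions, GC content, size) chosen
so the pocket factor is bimodal with opposite signs across archetypes:
the two pocket classes prefer opposite ends of the ligand spectrum, which
gives the benchmark genuine target specificity (a swap control destroys
performance) while staying learnable by a graph network from edge-label
statistics.  Ligand descriptors are composition fractions, representable
by a mean-pooled molecular-graph encoder.  Actives are the top oracle
quantile per pocket, computed without noise.

Lower oracle scores mean better (more negative energy), matching docking
conventions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .ligands import LigandRecord, smiles_to_ligand
from .pockets import (
    DEFAULT_RELATION_VOCAB,
    LW_ASYMMETRIC,
    LW_SYMMETRIC,
    PocketGraph,
    expand_context,
)
from .splits import GroupSplit, SimilarityMatrix, cluster_pockets, split_groups
from .train import Group, GroupedInteractionSet

__all__ = [
    "OracleParams",
    "SyntheticBenchmark",
    "gen_pocket",
    "gen_rna_with_pocket",
    "gen_library",
    "planted_oracle",
    "pocket_descriptor",
    "ligand_descriptor",
    "graph_overlap_similarity",
    "make_benchmark",
]

_NC_FAMILIES = tuple(f for f in LW_SYMMETRIC + LW_ASYMMETRIC if f != "cWW")


# ---------------------------------------------------------------------------
# RNA graph generation


def _lm_vector(signature: str, lm_dim: int, seed: int) -> np.ndarray:
    """Pseudo language-model features: a seeded Gaussian keyed by local context."""
    key = int.from_bytes(
        hashlib.sha256(f"{seed}|{signature}".encode()).digest()[:8], "little"
    ) % (2**31)
    return np.random.default_rng(key).normal(size=lm_dim)


def _build_rna(
    n: int,
    rng: np.random.Generator,
    window: tuple[int, int],
    archetype: str,
    background_nc: float = 0.08,
    two_chains: bool = False,
    lm_dim: int = 0,
    lm_seed: int = 0,
    pocket_id: str = "rna",
) -> PocketGraph:
    lo, hi = window
    in_window = lambda i: lo <= i < hi
    if archetype == "high":
        window_probs = np.array([0.05, 0.45, 0.45, 0.05])  # G/C-rich
        window_nc = 0.65
    else:
        window_probs = np.array([0.45, 0.05, 0.05, 0.45])  # A/U-rich
        window_nc = 0.02
    bg_probs = np.full(4, 0.25)
    nts = []
    for i in range(n):
        probs = window_probs if in_window(i) else bg_probs
        nts.append("ACGU"[rng.choice(4, p=probs)])

    split_at = n // 2 if two_chains else n
    ids = [
        (f"A.{i + 1}" if i < split_at else f"B.{i - split_at + 1}") for i in range(n)
    ]
    g = PocketGraph(pocket_id, DEFAULT_RELATION_VOCAB)
    for i in range(n):
        g.add_node(ids[i], nts[i], is_core=True)
    # backbone path per chain
    for i in range(n - 1):
        same_chain = (i < split_at - 1) or (i >= split_at)
        if same_chain:
            g.add_interaction(ids[i], ids[i + 1], "B53")
    # canonical stem: pair the two arms of the hairpin
    n_stem = max(2, n // 2 - 2)
    for i in range(n_stem):
        j = n - 1 - i
        if j - i > 3 and rng.random() < 0.7:
            g.add_interaction(ids[i], ids[j], "cWW")
    # sprinkled non-canonical pairs; window nodes pair within the window so
    # the planted archetype concentrates in the pocket core
    for i in range(n):
        dens = window_nc if in_window(i) else background_nc
        if rng.random() < dens:
            if in_window(i):
                lo_j, hi_j = lo, hi
            else:
                lo_j, hi_j = max(0, i - 8), min(n, i + 8)
            j = int(rng.integers(lo_j, hi_j))
            if abs(j - i) > 1 and not g.graph.has_edge(ids[i], ids[j]):
                fam = _NC_FAMILIES[rng.integers(len(_NC_FAMILIES))]
                g.add_interaction(ids[i], ids[j], fam)
    if lm_dim:
        for node in g.node_ids:
            incident = sorted(
                d["label"] for _, _, d in g.graph.out_edges(node, data=True)
            )
            sig = f"{g.graph.nodes[node]['nt']}|{','.join(incident)}"
            g.graph.nodes[node]["lm"] = _lm_vector(sig, lm_dim, lm_seed)
    g.validate()
    return g


def gen_pocket(
    n_residues: int,
    seed: int = 0,
    archetype: str | None = None,
    lm_dim: int = 0,
) -> PocketGraph:
    """A standalone binding-site graph of ``n_residues`` nucleotides."""
    if n_residues < 5:
        raise ValueError("pockets need at least 5 residues (extraction filter)")
    rng = np.random.default_rng(seed)
    if archetype is None:
        archetype = "high" if rng.random() < 0.5 else "low"
    return _build_rna(
        n_residues,
        rng,
        window=(0, n_residues),
        archetype=archetype,
        two_chains=bool(rng.random() < 0.3) and n_residues >= 10,
        lm_dim=lm_dim,
        lm_seed=seed,
        pocket_id=f"pocket_{seed}",
    )


def gen_rna_with_pocket(
    n_total: int,
    pocket_size: int,
    seed: int = 0,
    archetype: str | None = None,
    lm_dim: int = 0,
    pocket_id: str = "p",
) -> tuple[PocketGraph, set]:
    """A whole RNA with a planted pocket window; returns (whole, core ids)."""
    if pocket_size < 5 or n_total < pocket_size:
        raise ValueError("need n_total >= pocket_size >= 5")
    rng = np.random.default_rng(seed)
    if archetype is None:
        archetype = "high" if rng.random() < 0.5 else "low"
    lo = int(rng.integers(0, n_total - pocket_size + 1))
    whole = _build_rna(
        n_total,
        rng,
        window=(lo, lo + pocket_size),
        archetype=archetype,
        lm_dim=lm_dim,
        lm_seed=seed,
        pocket_id=f"{pocket_id}_whole",
    )
    ids = whole.node_ids
    # node ids sort lexicographically; rebuild positional order
    order = sorted(ids, key=lambda s: (s.split(".")[0], int(s.split(".")[1])))
    core = set(order[lo : lo + pocket_size])
    return whole, core


def _mutate_rna(whole: PocketGraph, seed: int, n_nt_changes: int = 1) -> PocketGraph:
    """A near-duplicate: copy with a couple of nucleotide identities changed."""
    rng = np.random.default_rng(seed)
    out = PocketGraph(whole.pocket_id + "_dup", whole.relation_vocab)
    out.graph = whole.graph.copy()
    nodes = out.node_ids
    for _ in range(n_nt_changes):
        node = nodes[rng.integers(len(nodes))]
        current = out.graph.nodes[node]["nt"]
        choices = [x for x in "ACGU" if x != current]
        out.graph.nodes[node]["nt"] = choices[rng.integers(3)]
    return out


# ---------------------------------------------------------------------------
# compound library generation

_CORES = (
    "c1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1cnc({R})cn1",
    "C1CCN({R})CC1",
    "C1CCC({R})CC1",
    "c1csc({R})c1",
    "c1[nH]c({R})cc1",
    "O=C1NC(=O)c2ccccc12",  # phthalimide, no slot
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCO", "O", "OC", "N", "NC", "CO", "CN",
    "F", "Cl", "Br", "C(F)(F)F", "C#N",
    "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NC", "S(=O)(=O)N",
    "N(C)C", "OCC", "NCC", "OCCO",
    "c1ccccc1", "C1CCCCC1", "N1CCOCC1",
    # bulky / flexible tails that tend to fail the drug-likeness rules
    "CCCCCCCC", "OCCOCCOCCO", "C(=O)NCCCCCCN", "CCCCC(=O)OCCCC",
)


def gen_library(n_compounds: int, seed: int = 0) -> list[LigandRecord]:
    """A seeded library of parsable, mostly drug-like compounds.

    Compounds are assembled from a small template grammar (ring cores with
    substituent slots); the substituent mix is biased so roughly 8 in 10
    pass the drug-likeness filter, the remainder failing on flexibility,
    acceptor count or weight as a real vendor library would.
    """
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < n_compounds and attempts < 50 * n_compounds:
        attempts += 1
        core = _CORES[rng.integers(len(_CORES))]
        if "{R}" in core:
            sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            smiles = core.replace("{R}", sub)
            if rng.random() < 0.35:  # second decoration, prefix position
                sub2 = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
                smiles = f"{sub2}{smiles}" if not sub2[0].isdigit() else smiles
        else:
            smiles = core
        if Chem.MolFromSmiles(smiles) is None:
            continue
        out.append(smiles_to_ligand(smiles, f"lig{len(out):04d}"))
    if len(out) < n_compounds:
        raise RuntimeError("library generation failed to produce enough molecules")
    return out


# ---------------------------------------------------------------------------
# planted docking oracle


def pocket_descriptor(g: PocketGraph, core_only: bool = False) -> np.ndarray:
    """Hand-crafted pocket statistics the oracle (and models) can see.

    [1, frac non-canonical interactions, frac cWW, frac G/C nucleotides,
    frac A, mean degree / 4, n_nodes / 20].  By default computed over the
    full (context-expanded) graph -- the same view the graph network gets,
    which makes the planted oracle learnable by construction; pass
    ``core_only=True`` to restrict to the pocket core.
    """
    core = g.core_ids if core_only else set(g.graph.nodes)
    sub = g.graph.subgraph(core)
    pairs = set()
    for u, v, d in sub.edges(data=True):
        key = (min(u, v), max(u, v))
        lab = d["label"]
        canon = lab if lab in ("B53", "cWW") else ("B53" if lab == "B35" else lab)
        pairs.add((key, canon if canon in ("B53", "cWW") else "NC"))
    n_edges = len(pairs) or 1
    n_nc = sum(1 for _, lab in pairs if lab == "NC")
    n_cww = sum(1 for _, lab in pairs if lab == "cWW")
    nts = [sub.nodes[n]["nt"] for n in sub.nodes]
    n_nodes = len(nts) or 1
    frac_gc = sum(1 for x in nts if x in "GC") / n_nodes
    frac_a = sum(1 for x in nts if x == "A") / n_nodes
    mean_deg = (2 * len(pairs)) / n_nodes
    return np.array(
        [1.0, n_nc / n_edges, n_cww / n_edges, frac_gc, frac_a, mean_deg / 4.0, n_nodes / 20.0]
    )


def ligand_descriptor(lig: LigandRecord) -> np.ndarray:
    """Composition fractions of a molecule: [1, aromatic, N, O, in-ring, Csp3]."""
    mol = lig.mol
    n = mol.GetNumAtoms() or 1
    frac_arom = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / n
    frac_n = sum(a.GetSymbol() == "N" for a in mol.GetAtoms()) / n
    frac_o = sum(a.GetSymbol() == "O" for a in mol.GetAtoms()) / n
    frac_ring = sum(a.IsInRing() for a in mol.GetAtoms()) / n
    fcsp3 = rdMolDescriptors.CalcFractionCSP3(mol)
    return np.array([1.0, frac_arom, frac_n, frac_o, frac_ring, fcsp3])


@dataclass
class OracleParams:
    """Planted weights and noise scale of the synthetic docking oracle."""

    w_pocket: np.ndarray
    w_ligand: np.ndarray
    sigma: float
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, sigma: float = 0.0) -> "OracleParams":
        rng = np.random.default_rng(seed)
        # frac_nc, frac_gc carry the archetype; centred so the pocket factor
        # is bimodal with opposite signs across the two archetypes
        w_p = np.array([-2.3, 12.0, 0.5, 2.5, 0.0, 0.0, 0.0])
        w_l = np.array([0.3, 1.2, 1.0, 0.8, 0.5, -0.6])
        w_p = w_p + rng.normal(scale=0.02, size=w_p.shape)
        w_l = w_l + rng.normal(scale=0.02, size=w_l.shape)
        return cls(w_pocket=w_p, w_ligand=w_l, sigma=sigma, seed=seed)


def _pair_noise(params: OracleParams, pocket_id: str, ligand_id: str) -> float:
    key = int.from_bytes(
        hashlib.sha256(f"{params.seed}|{pocket_id}|{ligand_id}".encode()).digest()[:8],
        "little",
    ) % (2**31)
    return float(np.random.default_rng(key).normal())


def planted_oracle(
    pocket: PocketGraph,
    lig: LigandRecord,
    params: OracleParams,
    sigma: float | None = None,
) -> float:
    """Synthetic docking score (lower = better), deterministic per (seed, pair)."""
    s = sigma if sigma is not None else params.sigma
    base = -float(params.w_pocket @ pocket_descriptor(pocket)) * float(
        params.w_ligand @ ligand_descriptor(lig)
    )
    if s > 0:
        base += s * _pair_noise(params, pocket.pocket_id, lig.ligand_id)
    return base


# ---------------------------------------------------------------------------
# similarity stand-in


def graph_overlap_similarity(graphs: dict[str, PocketGraph]) -> SimilarityMatrix:
    """Graph-overlap pocket similarity: Jaccard of Weisfeiler-Lehman node signatures.

    A structural stand-in for alignment-based binding-site similarity:
    near-identical pockets share almost all refined node signatures,
    unrelated pockets share few.
    """
    import warnings

    import networkx as nx

    ids = sorted(graphs)
    sigs = {}
    for pid in ids:
        with warnings.catch_warnings():
            # nx warns that directed WL hashes changed in 3.5; only internal
            # consistency within one run matters here
            warnings.simplefilter("ignore", UserWarning)
            hashes = nx.weisfeiler_lehman_subgraph_hashes(
                graphs[pid].graph, node_attr="nt", edge_attr="label", iterations=2
            )
        sigs[pid] = {h[-1] for h in hashes.values()}
    n = len(ids)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sigs[ids[i]], sigs[ids[j]]
            union = len(a | b)
            M[i, j] = M[j, i] = (len(a & b) / union) if union else 1.0
    return SimilarityMatrix(ids, M, metric_name="wl_overlap")


# ---------------------------------------------------------------------------
# benchmark assembly


@dataclass
class SyntheticBenchmark:
    """A complete desk-scale screening benchmark with planted ground truth."""

    pockets: dict[str, PocketGraph]  # context-expanded, core flags set
    wholes: dict[str, PocketGraph]
    library: list[LigandRecord]
    oracle: OracleParams
    dock_table: pd.DataFrame  # pocket_id, ligand_id, raw_score (noisy)
    noiseless_table: pd.DataFrame
    actives: dict[str, set]
    sim_matrix: SimilarityMatrix
    split: GroupSplit
    interactions: GroupedInteractionSet
    seed: int

    @property
    def ligands(self) -> dict[str, LigandRecord]:
        return {l.ligand_id: l for l in self.library}

    def test_group_ids(self) -> list[int]:
        return sorted(g for g, part in self.split.assignment.items() if part == "test")

    def train_group_ids(self) -> list[int]:
        return sorted(g for g, part in self.split.assignment.items() if part == "train")

    def group_for_pocket(self, pocket_id: str) -> int:
        for gid, ids in self.split.groups.items():
            if pocket_id in ids:
                return gid
        raise KeyError(pocket_id)

    def interaction_subset(self, part: str) -> GroupedInteractionSet:
        """The grouped interactions of one split part ("train" or "test")."""
        keep_reps = {
            self.split.representatives[gid]
            for gid, p in self.split.assignment.items()
            if p == part
        }
        groups = [g for g in self.interactions.groups if g.group_id in keep_reps]
        dock = self.dock_table[self.dock_table["pocket_id"].isin(keep_reps)].reset_index(
            drop=True
        )
        return GroupedInteractionSet(groups, self.ligands, docking_scores=dock)


def simulate_complementary_heads(
    benchmark: "SyntheticBenchmark",
    pocket_ids: list[str],
    seed: int = 0,
    sigma_good: float = 0.3,
    sigma_bad: float = 1.2,
):
    """Two simulated scoring heads with complementary per-pocket noise.

    Mimics the observed complementarity of the two trained heads: each
    head tracks the noiseless oracle closely on one pocket archetype
    (noise ``sigma_good`` x score sd) and poorly on the other
    (``sigma_bad``), with the archetypes swapped between heads.  Returns
    per-pocket :class:`~rnascreen.screen.ScreenResult` pairs ready for
    rank-max mixing.
    """
    from .screen import make_screen_result

    rng = np.random.default_rng(seed)
    lig_ids = [l.ligand_id for l in benchmark.library]
    out_a, out_b = [], []
    for pid in pocket_ids:
        nl = benchmark.noiseless_table[
            benchmark.noiseless_table["pocket_id"] == pid
        ].set_index("ligand_id")
        true = -nl.loc[lig_ids, "raw_score"].to_numpy()  # higher = better
        sd = float(true.std())
        factor = float(benchmark.oracle.w_pocket @ pocket_descriptor(benchmark.pockets[pid]))
        sig_a, sig_b = (sigma_good, sigma_bad) if factor > 0 else (sigma_bad, sigma_good)
        sa = true + sig_a * sd * rng.normal(size=len(true))
        sb = true + sig_b * sd * rng.normal(size=len(true))
        out_a.append(make_screen_result(pid, lig_ids, sa, benchmark.actives[pid]))
        out_b.append(make_screen_result(pid, lig_ids, sb, benchmark.actives[pid]))
    return out_a, out_b


def make_benchmark(
    n_pockets: int = 20,
    n_compounds: int = 200,
    active_quantile: float = 0.05,
    noise_rel: float = 0.2,
    seed: int = 0,
    n_duplicate_pairs: int = 3,
    pocket_size: int = 12,
    rna_size: int = 60,
    context_depth: int = 4,
    test_fraction: float = 0.25,
    lm_dim: int = 0,
) -> SyntheticBenchmark:
    """Generate pockets, ligands, planted docking scores, actives and splits.

    ``noise_rel`` scales the oracle noise as a fraction of the noiseless
    score standard deviation across the full table; actives are the best
    ``active_quantile`` of the noiseless oracle per pocket.  The last
    ``n_duplicate_pairs`` pockets are near-duplicates of the first ones,
    planting similarity clusters the split machinery must keep together.
    """
    if n_pockets < 4:
        raise ValueError("need at least 4 pockets")
    rng = np.random.default_rng(seed)
    archetypes = ["high" if i % 2 == 0 else "low" for i in range(n_pockets)]

    wholes: dict[str, PocketGraph] = {}
    cores: dict[str, set] = {}
    n_fresh = n_pockets - n_duplicate_pairs
    for i in range(n_fresh):
        pid = f"pk{i:03d}"
        whole, core = gen_rna_with_pocket(
            rna_size, pocket_size, seed=int(rng.integers(2**31)),
            archetype=archetypes[i], lm_dim=lm_dim, pocket_id=pid,
        )
        whole.pocket_id = f"{pid}_whole"
        wholes[pid], cores[pid] = whole, core
    for k in range(n_duplicate_pairs):
        src = f"pk{k:03d}"
        pid = f"pk{n_fresh + k:03d}"
        dup = _mutate_rna(wholes[src], seed=int(rng.integers(2**31)))
        dup.pocket_id = f"{pid}_whole"
        wholes[pid], cores[pid] = dup, set(cores[src])

    pockets: dict[str, PocketGraph] = {}
    for pid, whole in wholes.items():
        core_graph = whole.subgraph(cores[pid], pocket_id=pid)
        core_graph.set_core(cores[pid])
        pockets[pid] = expand_context(core_graph, whole, depth=context_depth)

    library = gen_library(n_compounds, seed=seed + 1)
    ligands = {l.ligand_id: l for l in library}

    oracle = OracleParams.default(seed=seed)
    rows = []
    for pid, g in pockets.items():
        for lig in library:
            rows.append((pid, lig.ligand_id, planted_oracle(g, lig, oracle, sigma=0.0)))
    noiseless = pd.DataFrame(rows, columns=["pocket_id", "ligand_id", "raw_score"])
    sd = float(noiseless["raw_score"].std())
    oracle.sigma = noise_rel * sd
    dock = noiseless.copy()
    if oracle.sigma > 0:
        dock["raw_score"] = [
            s + oracle.sigma * _pair_noise(oracle, p, l)
            for p, l, s in dock.itertuples(index=False)
        ]

    n_act = int(round(active_quantile * n_compounds))
    actives: dict[str, set] = {}
    for pid, grp in noiseless.groupby("pocket_id"):
        best = grp.nsmallest(n_act, "raw_score")
        actives[pid] = set(best["ligand_id"])

    sim = graph_overlap_similarity(pockets)
    grouping = cluster_pockets(sim, cutoff=0.75)
    # both archetypes must appear among the test representatives, otherwise
    # the specificity (swap) control is vacuous on the test set; re-draw the
    # seeded assignment until the split is archetype-balanced
    factor = {
        pid: float(oracle.w_pocket @ pocket_descriptor(g)) for pid, g in pockets.items()
    }
    split = None
    for attempt in range(100):
        cand, _report = split_groups(
            grouping, sim, test_fraction=test_fraction, seed=seed + 1009 * attempt,
            cutoff=0.75,
        )
        signs = {
            factor[cand.representatives[gid]] > 0
            for gid, part in cand.assignment.items()
            if part == "test"
        }
        if signs == {True, False}:
            split = cand
            break
    if split is None:  # pragma: no cover - would need a degenerate generator
        split = cand

    groups = []
    for gid in sorted(split.groups):
        rep_id = split.representatives[gid]
        group_actives = sorted(set().union(*(actives[p] for p in split.groups[gid])))
        inactives = sorted(set(ligands) - set(group_actives))
        groups.append(
            Group(
                group_id=rep_id,
                representative=pockets[rep_id],
                actives=group_actives,
                inactives=inactives,
            )
        )
    interactions = GroupedInteractionSet(groups, ligands, docking_scores=dock)
    interactions.validate()

    return SyntheticBenchmark(
        pockets=pockets,
        wholes=wholes,
        library=library,
        oracle=oracle,
        dock_table=dock,
        noiseless_table=noiseless,
        actives=actives,
        sim_matrix=sim,
        split=split,
        interactions=interactions,
        seed=seed,
    )
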