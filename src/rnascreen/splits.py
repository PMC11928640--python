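"""Pocket clustering, leakage-free splitting, docking-manifest construction.

Binding sites recur across structures, so naive random splits leak
near-identical pockets between train and test.  The guard used here:
compute all pairwise pocket similarities (the metric is a pluggable
callable; a structural-alignment score in production, a graph-overlap
stand-in for synthetic data), cluster with single-linkage agglomerative
clustering cut at distance ``1 - cutoff`` (default cutoff 0.75), and
assign whole clusters to train or test.  Single linkage guarantees that
no cross-cluster pair has similarity >= cutoff, which is exactly the
no-structural-leakage property the split must certify.  Each group keeps
one representative pocket and pools the native ligands of its members as
group actives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SimilarityMatrix",
    "GroupSplit",
    "cluster_pockets",
    "split_groups",
    "docking_manifest",
]


@dataclass
class SimilarityMatrix:
    pocket_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]
    metric_name: str = "unknown"

    def validate(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pocket_ids), len(self.pocket_ids)):
            raise ValueError("similarity matrix shape does not match pocket ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must be within [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.pocket_ids, columns=self.pocket_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric_name: str = "unknown") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), metric_name)


@dataclass
class GroupSplit:
    groups: dict[int, list[str]]  # cluster id -> pocket ids
    representatives: dict[int, str] = field(default_factory=dict)
    assignment: dict[int, str] = field(default_factory=dict)  # cluster id -> train/test

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def pockets_in(self, part: str) -> list[str]:
        return [p for gid, ids in self.groups.items() if self.assignment.get(gid) == part for p in ids]


def cluster_pockets(sim: SimilarityMatrix, cutoff: float = 0.75) -> GroupSplit:
    """Single-linkage agglomerative clustering of pockets at a similarity cutoff.

    Works on distance ``1 - similarity`` and cuts the dendrogram at
    ``1 - cutoff``, merging every pair at similarity >= cutoff; by the
    single-linkage guarantee no cross-cluster pair reaches the cutoff.
    """
    sim.validate()
    n = len(sim.pocket_ids)
    if n == 1:
        return GroupSplit(groups={1: list(sim.pocket_ids)})
    dist = 1.0 - np.asarray(sim.values, dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for pid, lab in zip(sim.pocket_ids, labels):
        groups.setdefault(int(lab), []).append(pid)
    return GroupSplit(groups={gid: sorted(ids) for gid, ids in sorted(groups.items())})


def split_groups(
    split: GroupSplit,
    sim: SimilarityMatrix,
    test_fraction: float = 0.16,
    seed: int = 0,
    cutoff: float = 0.75,
    native_ligands: dict[str, str] | None = None,
) -> tuple[GroupSplit, dict]:
    """Assign whole groups to train/test and certify the leakage guarantee.

    Returns the completed :class:`GroupSplit` (seeded assignment and a
    seeded representative per group) and a leakage report with the maximum
    cross-split similarity; a cross-split pair at or above the cutoff
    raises (impossible with single-linkage clusters, by construction).
    When ``native_ligands`` (pocket_id -> ligand_id) is given, the report
    also carries each group's pooled group actives.
    """
    if split.n_groups < 2:
        raise ValueError("need at least 2 groups to split")
    rng = np.random.default_rng(seed)
    gids = sorted(split.groups)
    order = rng.permutation(len(gids))
    n_test = int(round(test_fraction * len(gids)))
    test_ids = {gids[i] for i in order[:n_test]}
    assignment = {gid: ("test" if gid in test_ids else "train") for gid in gids}
    representatives = {
        gid: split.groups[gid][rng.integers(len(split.groups[gid]))] for gid in gids
    }
    out = GroupSplit(split.groups, representatives, assignment)

    idx = {p: i for i, p in enumerate(sim.pocket_ids)}
    train_p = [idx[p] for p in out.pockets_in("train")]
    test_p = [idx[p] for p in out.pockets_in("test")]
    max_cross = 0.0
    worst = None
    if train_p and test_p:
        sub = np.asarray(sim.values)[np.ix_(train_p, test_p)]
        k = np.unravel_index(np.argmax(sub), sub.shape)
        max_cross = float(sub[k])
        worst = (sim.pocket_ids[train_p[k[0]]], sim.pocket_ids[test_p[k[1]]])
    if max_cross >= cutoff:
        raise ValueError(
            f"structural leakage: cross-split pair {worst} has similarity {max_cross:.3f}"
        )
    report = {
        "max_cross_split_similarity": max_cross,
        "worst_pair": worst,
        "n_train_groups": sum(1 for g in assignment.values() if g == "train"),
        "n_test_groups": sum(1 for g in assignment.values() if g == "test"),
    }
    if native_ligands is not None:
        report["group_actives"] = {
            gid: sorted({native_ligands[p] for p in ids if p in native_ligands})
            for gid, ids in split.groups.items()
        }
    return out, report


def docking_manifest(pockets: list[str], ligands: list[str]) -> pd.DataFrame:
    """Cartesian docking job table: one deduplicated row per (pocket, ligand)."""
    if not pockets or not ligands:
        raise ValueError("pockets and ligands must be non-empty")
    unique_p = list(dict.fromkeys(pockets))
    unique_l = list(dict.fromkeys(ligands))
    if len(unique_p) < len(pockets) or len(unique_l) < len(ligands):
        import warnings

        warnings.warn("duplicate ids collapsed in docking manifest", stacklevel=2)
    return pd.DataFrame(
        {
            "pocket_id": np.repeat(np.asarray(unique_p, dtype=object), len(unique_l)),
            "ligand_id": np.tile(np.asarray(unique_l, dtype=object), len(unique_p)),
        }
    )
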