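"""Library scoring, ensembling, budgeted hybrid screening and VS metrics.

A virtual screen ranks a compound library so that active compounds
concentrate at the top.  This module holds the per-pocket screen result
container and every evaluation used by the pipeline:

* AuROC (Mann-Whitney convention, ties count 1/2) and enrichment factors
  EF@X% = (actives in top X% / top-X% size) / (actives / N);
* rank-max ensembling ("Mixed"): each compound is keyed by the best of
  its per-head rank positions;
* hybrid budgeted screening: presort with the fast surrogate, then spend
  a docking time budget on the top of the list and replace surrogate
  scores with true docking values;
* the efficiency statistic: area under (or between) AuROC-versus-time
  curves, averaged over shuffled initial library orders;
* the swap (shuffled-target) specificity control and chemical-diversity
  metrics (nearest-neighbour Tanimoto distance, Hopkins statistic).

Simulated per-compound costs default to the package's cost model
(surrogate 5.8 ms, docking 65 s per compound) and are used only for
budget accounting; they are hardware-dependent figures, not measurements
of this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from .ligands import LigandRecord, tanimoto

__all__ = [
    "CostModel",
    "ScreenResult",
    "EfficiencyCurve",
    "EfficiencyResult",
    "make_screen_result",
    "auroc",
    "enrichment_factor",
    "mix_ranks",
    "hybrid_screen",
    "efficiency",
    "swap_experiment",
    "diversity_metrics",
    "mannwhitney_test",
]


@dataclass(frozen=True)
class CostModel:
    """Simulated per-compound evaluation costs in seconds."""

    surrogate_cost_per_compound: float = 0.0058
    docking_cost_per_compound: float = 65.0


@dataclass
class ScreenResult:
    """Per-compound scores, ranks and labels for one pocket.

    ``table`` columns: ligand_id, score, rank, is_active, cost.  Ranks are
    a permutation of 1..N (1 = best); higher scores are better; ties are
    broken by ligand_id for determinism.
    """

    pocket_id: str
    table: pd.DataFrame
    cost_model: CostModel = field(default_factory=CostModel)

    @property
    def n(self) -> int:
        return len(self.table)

    def ordered(self) -> pd.DataFrame:
        return self.table.sort_values("rank")


def _rank_scores(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["score", "ligand_id"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def make_screen_result(
    pocket_id: str,
    ligand_ids,
    scores,
    active_ids,
    cost_model: CostModel | None = None,
    cost_per_compound: float | None = None,
) -> ScreenResult:
    cost_model = cost_model or CostModel()
    if cost_per_compound is None:
        cost_per_compound = cost_model.surrogate_cost_per_compound
    df = pd.DataFrame(
        {
            "ligand_id": list(ligand_ids),
            "score": np.asarray(scores, dtype=float),
            "is_active": [l in set(active_ids) for l in ligand_ids],
        }
    )
    df = _rank_scores(df)
    df["cost"] = cost_per_compound
    return ScreenResult(pocket_id, df, cost_model)


# ---------------------------------------------------------------------------
# core metrics


def auroc(scores, labels) -> float:
    """Probability that a random active outranks a random inactive.

    Ties count one half (Mann-Whitney convention).  Raises if only one
    class is present.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("AuROC needs at least one active and one inactive")
    return float(roc_auc_score(labels, scores))


def enrichment_factor(result: ScreenResult, cutoff_pct: float) -> float:
    """EF@X%: active rate in the top X% of the ranking over the base rate."""
    if not 0 < cutoff_pct <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    n = result.n
    top_size = int(np.floor(n * cutoff_pct / 100.0))
    if top_size == 0:
        raise ValueError(f"top {cutoff_pct}% of {n} compounds is empty")
    df = result.table
    n_actives = int(df["is_active"].sum())
    actives_top = int(df.loc[df["rank"] <= top_size, "is_active"].sum())
    return (actives_top / top_size) / (n_actives / n)


def mannwhitney_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two score samples."""
    stat, p = mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# ensembling and hybrid screening


def mix_ranks(result_a: ScreenResult, result_b: ScreenResult) -> ScreenResult:
    """Rank-max ("Mixed") ensemble of two screens over the same library.

    Each compound is keyed by the best (numerically smallest) of its two
    rank positions; ties are broken by the mean of the two ranks, then by
    ligand_id.
    """
    ids_a = set(result_a.table["ligand_id"])
    ids_b = set(result_b.table["ligand_id"])
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise ValueError(f"compound sets differ; symmetric difference: {diff}")
    a = result_a.table.set_index("ligand_id")
    b = result_b.table.set_index("ligand_id")
    key = pd.DataFrame(
        {
            "best": np.minimum(a["rank"], b["rank"]),
            "mean": (a["rank"] + b["rank"]) / 2.0,
            "is_active": a["is_active"],
        }
    )
    key = key.reset_index().sort_values(["best", "mean", "ligand_id"])
    df = pd.DataFrame(
        {
            "ligand_id": key["ligand_id"].to_numpy(),
            "score": -key["best"].to_numpy(dtype=float),
            "is_active": key["is_active"].to_numpy(),
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["cost"] = result_a.table["cost"].iloc[0] + result_b.table["cost"].iloc[0]
    return ScreenResult(result_a.pocket_id, df.reset_index(drop=True), result_a.cost_model)


def hybrid_screen(
    presort: ScreenResult,
    docking_scores,
    budget: float,
    cost_model: CostModel | None = None,
) -> ScreenResult:
    """Budgeted presort-then-dock screening.

    Compounds are docked in presort rank order until the time budget is
    exhausted; docked compounds are re-scored by their true docking energy
    (lower = better) and placed above all undocked compounds, which retain
    the presort order.  ``docking_scores`` is a mapping or callable
    ligand_id -> docking energy.  The returned table records each
    compound's cumulative simulated cost.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    cost_model = cost_model or presort.cost_model
    lookup = docking_scores if callable(docking_scores) else docking_scores.__getitem__
    n_dock = min(int(np.floor(budget / cost_model.docking_cost_per_compound)), presort.n)
    ordered = presort.ordered().reset_index(drop=True)
    docked = ordered.iloc[:n_dock].copy()
    undocked = ordered.iloc[n_dock:].copy()
    energies = []
    for lid in docked["ligand_id"]:
        try:
            energies.append(float(lookup(lid)))
        except KeyError as exc:
            raise KeyError(f"missing docking value for compound {lid!r}") from exc
    docked["score"] = [-e for e in energies]  # lower energy = better = higher score
    docked = docked.sort_values(["score", "ligand_id"], ascending=[False, True])
    docked["cost"] = presort.table["cost"].iloc[0] + cost_model.docking_cost_per_compound * np.arange(
        1, len(docked) + 1
    )
    out = pd.concat([docked, undocked], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return ScreenResult(presort.pocket_id, out, cost_model)


# ---------------------------------------------------------------------------
# efficiency


@dataclass
class EfficiencyCurve:
    budgets: np.ndarray  # seconds, strictly increasing, from 0 to total cost
    auroc_at_budget: np.ndarray

    def at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.budgets, self.auroc_at_budget)

    @property
    def total_time(self) -> float:
        return float(self.budgets[-1])


@dataclass
class EfficiencyResult:
    value: float
    se: float
    curves: list[EfficiencyCurve]
    per_replicate: np.ndarray


def _auroc_of_ranking(order: np.ndarray, labels: np.ndarray) -> float:
    # order[0] is the best-ranked item; AuROC of the induced full ranking
    pseudo = np.empty(len(order))
    pseudo[order] = -np.arange(len(order), dtype=float)
    return auroc(pseudo, labels)


def _stream_curve(
    scores: np.ndarray, labels: np.ndarray, initial_order: np.ndarray, cost_per_item: float
) -> EfficiencyCurve:
    n = len(scores)
    budgets = np.arange(n + 1, dtype=float) * cost_per_item
    values = np.empty(n + 1)
    for k in range(n + 1):
        processed = list(initial_order[:k])
        processed.sort(key=lambda i: (-scores[i], i))
        order = np.array(processed + list(initial_order[k:]), dtype=int)
        values[k] = _auroc_of_ranking(order, labels)
    return EfficiencyCurve(budgets, values)


def efficiency(
    scores,
    labels,
    cost_per_item: float,
    reference: EfficiencyCurve | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
    initial_order=None,
) -> EfficiencyResult:
    """Area under (or between) the AuROC-versus-time screening curve.

    Compounds are processed in an initial order at ``cost_per_item``
    seconds each; at any time the processed compounds are ranked by their
    scores and unprocessed ones follow in their initial order at the end
    of the list.  The AuROC of that full ranking against the labels,
    traced against cumulative cost and integrated by the trapezoid rule
    over normalized time, is the (absolute) efficiency.  With a
    ``reference`` curve the value is the area between the two curves
    (method minus reference) over the longer of the two time spans.  The
    expectation over initial orders is estimated from ``n_shuffles``
    seeded shuffles (mean with standard error), unless a fixed
    ``initial_order`` is supplied.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if cost_per_item <= 0:
        raise ValueError("cost per item must be positive")
    rng = np.random.default_rng(seed)
    if initial_order is not None:
        orders = [np.asarray(initial_order, dtype=int)]
    else:
        orders = [rng.permutation(len(scores)) for _ in range(n_shuffles)]
    curves = [_stream_curve(scores, labels, o, cost_per_item) for o in orders]
    vals = []
    for c in curves:
        if reference is None:
            total = c.total_time
            vals.append(float(np.trapezoid(c.auroc_at_budget, c.budgets) / total))
        else:
            total = max(c.total_time, reference.total_time)
            grid = np.union1d(c.budgets, reference.budgets)
            grid = grid[grid <= total]
            if grid[-1] < total:
                grid = np.append(grid, total)
            diff = c.at(grid) - reference.at(grid)
            vals.append(float(np.trapezoid(diff, grid) / total))
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return EfficiencyResult(float(vals.mean()), se, curves, vals)


# ---------------------------------------------------------------------------
# specificity and diversity


def swap_experiment(results: list[ScreenResult], seed: int = 0) -> dict:
    """Shuffled-target specificity control.

    Reassigns each pocket's active-compound set to another pocket by a
    seeded derangement (no pocket keeps its own actives) and recomputes
    per-pocket AuROC against the swapped labels.  Reports mean true and
    swapped AuROC and their gap.
    """
    if len(results) < 2:
        raise ValueError("swap experiment needs at least 2 pockets")
    rng = np.random.default_rng(seed)
    n = len(results)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    active_sets = [set(r.table.loc[r.table["is_active"], "ligand_id"]) for r in results]
    true_vals, swapped_vals = [], []
    for i, r in enumerate(results):
        scores = r.table["score"].to_numpy()
        true_labels = r.table["is_active"].to_numpy()
        swapped = r.table["ligand_id"].isin(active_sets[perm[i]]).to_numpy()
        true_vals.append(auroc(scores, true_labels))
        swapped_vals.append(auroc(scores, swapped))
    mean_true = float(np.mean(true_vals))
    mean_swapped = float(np.mean(swapped_vals))
    return {
        "assignment": perm,
        "auroc_true": np.array(true_vals),
        "auroc_swapped": np.array(swapped_vals),
        "mean_true": mean_true,
        "mean_swapped": mean_swapped,
        "gap": mean_true - mean_swapped,
    }


def diversity_metrics(
    selected: list[LigandRecord],
    background: list[LigandRecord] | None = None,
    seed: int = 0,
    n_probes: int | None = None,
) -> dict:
    """Chemical diversity of a selected compound set.

    * nearest-neighbour distance: mean over selected compounds of the
      minimum Tanimoto distance to any other selected compound;
    * Hopkins statistic of the selected set in fingerprint space, with
      seeded probe points drawn bit-wise from the empirical bit
      frequencies of the background (default: the selected set itself).
      Values near 0.5 indicate no clustering tendency; near 1, strong
      clustering.
    """
    if len(selected) < 2:
        raise ValueError("diversity metrics need at least 2 compounds")
    fps = np.array([l.fingerprint for l in selected], dtype=bool)
    n = len(fps)
    sims = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims[i, j] = sims[j, i] = tanimoto(fps[i], fps[j])
    dist = 1.0 - sims
    np.fill_diagonal(dist, np.inf)
    nn_dist = float(dist.min(axis=1).mean())

    rng = np.random.default_rng(seed)
    bg = np.array([l.fingerprint for l in (background or selected)], dtype=bool)
    p_bit = bg.mean(axis=0)
    m = n_probes or min(n, 50)
    probes = rng.random((m, fps.shape[1])) < p_bit
    sample_idx = rng.choice(n, size=m, replace=False) if m <= n else rng.integers(0, n, m)

    def min_tani_dist(x, pool, skip=None):
        best = np.inf
        for idx in range(len(pool)):
            if skip is not None and idx == skip:
                continue
            best = min(best, 1.0 - tanimoto(x, pool[idx]))
        return best

    u = np.array([min_tani_dist(pr, fps) for pr in probes])
    w = np.array([min_tani_dist(fps[i], fps, skip=i) for i in sample_idx])
    denom = u.sum() + w.sum()
    hopkins = float(u.sum() / denom) if denom > 0 else 0.5
    return {"nn_tanimoto_distance": nn_dist, "hopkins": hopkins}
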