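"""Virtual-screening metrics, ensembling, hybrid screening, efficiency."""

import numpy as np
import pandas as pd
import pytest

from rnascreen.ligands import smiles_to_ligand
from rnascreen.screen import (
    CostModel,
    EfficiencyCurve,
    auroc,
    diversity_metrics,
    efficiency,
    enrichment_factor,
    hybrid_screen,
    make_screen_result,
    mix_ranks,
    swap_experiment,
)


def pair_count_auroc(scores, labels):
    """Exhaustive pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ranking_is_one(self):
        assert auroc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_hand_case_three_quarters(self):
        assert auroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_equals_pair_count_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # rounded to force ties
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                pair_count_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestEnrichmentFactor:
    def _result(self, n, active_ranks):
        scores = -np.arange(n, dtype=float)  # rank i+1 has score -i
        ids = [f"l{i:04d}" for i in range(n)]
        actives = {ids[r - 1] for r in active_ranks}
        return make_screen_result("p", ids, scores, actives)

    def test_printed_hand_case(self):
        # 1000 compounds, 10 actives, 3 of them in the top 10 (top 1%)
        res = self._result(1000, [1, 5, 9] + list(range(500, 507)))
        assert enrichment_factor(res, 1.0) == pytest.approx(30.0)

    def test_ef_at_full_library_is_exactly_one(self):
        res = self._result(200, [3, 77, 120])
        assert enrichment_factor(res, 100.0) == 1.0

    def test_no_actives_in_top_is_zero(self):
        res = self._result(100, [90, 95])
        assert enrichment_factor(res, 5.0) == 0.0

    def test_random_ranking_has_null_expectation_one(self):
        rng = np.random.default_rng(1)
        n, k = 100, 10
        vals = []
        ids = [f"l{i}" for i in range(n)]
        for _ in range(1000):
            scores = rng.permutation(n).astype(float)
            actives = set(rng.choice(ids, size=k, replace=False))
            vals.append(enrichment_factor(make_screen_result("p", ids, scores, actives), 10.0))
        assert abs(np.mean(vals) - 1.0) < 0.2

    def test_empty_top_set_errors(self):
        res = self._result(50, [2])
        with pytest.raises(ValueError):
            enrichment_factor(res, 1.0)  # top 1% of 50 is empty


class TestMixRanks:
    def _pair(self, ranks_a, ranks_b, actives=()):
        ids = [f"c{i}" for i in range(len(ranks_a))]
        sa = [-r for r in ranks_a]
        sb = [-r for r in ranks_b]
        return (
            make_screen_result("p", ids, sa, set(actives)),
            make_screen_result("p", ids, sb, set(actives)),
        )

    def test_best_rank_wins(self):
        a, b = self._pair([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                          [10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        mixed = mix_ranks(a, b)
        row = mixed.table.set_index("ligand_id").loc["c0"]
        assert row["score"] == -1.0  # ranked 1st by model A, 10th by B

    def test_idempotent_on_identical_rankings(self):
        a, b = self._pair([3, 1, 2], [3, 1, 2])
        mixed = mix_ranks(a, b)
        assert list(mixed.table.sort_values("rank")["ligand_id"]) == ["c1", "c2", "c0"]

    def test_three_compound_hand_enumeration(self):
        # A ranks (1,2,3), B ranks (3,1,2): keys (1,1,2); the key tie between
        # c0 (mean 2) and c1 (mean 1.5) resolves to c1 first
        a, b = self._pair([1, 2, 3], [3, 1, 2])
        mixed = mix_ranks(a, b)
        assert list(mixed.table.sort_values("rank")["ligand_id"]) == ["c1", "c0", "c2"]

    def test_compound_set_mismatch_reports_difference(self):
        a, _ = self._pair([1, 2], [2, 1])
        c = make_screen_result("p", ["c0", "cX"], [0.0, 1.0], set())
        with pytest.raises(ValueError, match="cX"):
            mix_ranks(a, c)

    def test_dominance_over_best_single_model_rank(self):
        rng = np.random.default_rng(4)
        n = 30
        a, b = self._pair(rng.permutation(n) + 1, rng.permutation(n) + 1)
        mixed = mix_ranks(a, b).table.set_index("ligand_id")
        ra = a.table.set_index("ligand_id")["rank"]
        rb = b.table.set_index("ligand_id")["rank"]
        best = np.minimum(ra, rb)
        for lid in ra.index:
            # a compound can never be placed below the count of compounds
            # whose best single-model rank is at least as good as its own
            assert mixed.loc[lid, "rank"] <= int((best <= best[lid]).sum())


class TestHybridScreen:
    def _setup(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(n)]
        true_energy = {i: float(e) for i, e in zip(ids, rng.normal(size=n))}
        actives = set(sorted(ids, key=lambda i: true_energy[i])[:3])
        surrogate = {i: -true_energy[i] + rng.normal(scale=0.8) for i in ids}
        presort = make_screen_result("p", ids, [surrogate[i] for i in ids], actives)
        return presort, true_energy

    def test_zero_budget_returns_presort_order(self):
        presort, energy = self._setup()
        out = hybrid_screen(presort, energy, budget=0.0)
        assert list(out.ordered()["ligand_id"]) == list(presort.ordered()["ligand_id"])

    def test_full_budget_is_pure_docking_order(self):
        presort, energy = self._setup()
        cm = CostModel(docking_cost_per_compound=1.0)
        out = hybrid_screen(presort, energy, budget=100.0, cost_model=cm)
        expected = sorted(energy, key=lambda i: (energy[i], i))
        assert list(out.ordered()["ligand_id"]) == expected

    def test_partial_budget_matches_step_through_oracle(self):
        presort, energy = self._setup(n=10, seed=3)
        cm = CostModel(docking_cost_per_compound=1.0)
        out = hybrid_screen(presort, energy, budget=4.0, cost_model=cm)
        # hand simulation: dock top-4 of presort, sort them by energy,
        # keep the rest in presort order behind them
        presort_order = list(presort.ordered()["ligand_id"])
        docked = sorted(presort_order[:4], key=lambda i: (energy[i], i))
        expected = docked + presort_order[4:]
        assert list(out.ordered()["ligand_id"]) == expected
        docked_costs = out.ordered()["cost"].iloc[:4].to_numpy()
        assert docked_costs.max() == pytest.approx(
            presort.table["cost"].iloc[0] + 4 * cm.docking_cost_per_compound
        )

    def test_negative_budget_and_missing_scores_error(self):
        presort, energy = self._setup()
        with pytest.raises(ValueError):
            hybrid_screen(presort, energy, budget=-1.0)
        energy.pop("c0")
        with pytest.raises(KeyError, match="c0"):
            hybrid_screen(presort, energy, budget=1000.0,
                          cost_model=CostModel(docking_cost_per_compound=1.0))


class TestEfficiency:
    def test_three_event_stream_matches_hand_trapezoid(self):
        # 3 compounds, 1 active; fixed processing order c0, c1, c2 at 2 s each.
        scores = np.array([1.0, 3.0, 2.0])
        labels = np.array([False, True, False])
        res = efficiency(scores, labels, cost_per_item=2.0, initial_order=[0, 1, 2])
        # k=0: order c0,c1,c2 -> active in middle -> AuROC 0.5
        # k=1: processed {c0} -> same ranking -> 0.5
        # k=2: {c1,c0} sorted -> c1 first -> 1.0 ; k=3 -> 1.0
        # trapezoid over t=0,2,4,6 of (.5,.5,1,1) / 6 = (1 + 1.5 + 2) / 6
        assert res.value == pytest.approx((1.0 + 1.5 + 2.0) / 6.0)

    def test_self_comparison_gives_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=12)
        labels = rng.random(12) < 0.25
        labels[0] = True
        labels[1] = False
        base = efficiency(scores, labels, 1.0, initial_order=np.arange(12))
        rel = efficiency(scores, labels, 1.0, reference=base.curves[0],
                         initial_order=np.arange(12))
        assert rel.value == pytest.approx(0.0, abs=1e-12)

    def test_constant_curves_relative_value(self):
        # perfect method curve (AuROC == 1 throughout) against a flat 0.5 line
        scores = np.array([5.0, 4.0, 1.0, 0.5])
        labels = np.array([True, True, False, False])
        ref = EfficiencyCurve(np.array([0.0, 4.0]), np.array([0.5, 0.5]))
        res = efficiency(scores, labels, 1.0, reference=ref,
                         initial_order=np.arange(4))
        assert res.value == pytest.approx(0.5)

    def test_presorted_beats_random_ordering(self, small_benchmark):
        b = small_benchmark
        pid = sorted(b.pockets)[0]
        lig_ids = [l.ligand_id for l in b.library]
        nl = b.noiseless_table[b.noiseless_table.pocket_id == pid].set_index("ligand_id")
        scores = -nl.loc[lig_ids, "raw_score"].to_numpy()
        labels = np.array([l in b.actives[pid] for l in lig_ids])
        random_eff = efficiency(scores, labels, 1.0, n_shuffles=10, seed=0)
        presorted = efficiency(scores, labels, 1.0, initial_order=np.argsort(-scores))
        assert presorted.value >= random_eff.value

    def test_invalid_cost_errors(self):
        with pytest.raises(ValueError):
            efficiency([1.0, 2.0], [True, False], cost_per_item=0.0)


class TestSwapExperiment:
    def _results(self, seed=0, n_pockets=5, n=40, k=5):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(n)]
        out = []
        for p in range(n_pockets):
            scores = rng.normal(size=n)
            actives = set(np.array(ids)[np.argsort(-scores)[:k]])
            out.append(make_screen_result(f"p{p}", ids, scores, actives))
        return out

    def test_assignment_is_a_derangement_and_deterministic(self):
        results = self._results()
        rep = swap_experiment(results, seed=3)
        assert not np.any(rep["assignment"] == np.arange(len(results)))
        rep2 = swap_experiment(results, seed=3)
        assert np.array_equal(rep["assignment"], rep2["assignment"])

    def test_needs_two_pockets(self):
        with pytest.raises(ValueError):
            swap_experiment(self._results()[:1], seed=0)

    def test_swapping_destroys_planted_signal(self, small_benchmark):
        b = small_benchmark
        lig_ids = [l.ligand_id for l in b.library]
        results = []
        for pid in sorted(b.pockets):
            nl = b.noiseless_table[b.noiseless_table.pocket_id == pid].set_index("ligand_id")
            scores = -nl.loc[lig_ids, "raw_score"].to_numpy()
            results.append(make_screen_result(pid, lig_ids, scores, b.actives[pid]))
        for seed in range(3):
            rep = swap_experiment(results, seed=seed)
            assert rep["mean_swapped"] < rep["mean_true"]
            # ties between duplicate library molecules can shave a little
            # off the oracle's otherwise perfect self-consistency
            assert rep["mean_true"] > 0.99


class FingerprintStub:
    def __init__(self, fingerprint):
        self.fingerprint = fingerprint


class TestDiversityMetrics:
    def test_duplicates_have_zero_nn_distance(self):
        lig = smiles_to_ligand("c1ccccc1", "a")
        dup = smiles_to_ligand("c1ccccc1", "b")
        metrics = diversity_metrics([lig, dup])
        assert metrics["nn_tanimoto_distance"] == 0.0

    def test_nn_distance_within_unit_interval(self, small_library):
        metrics = diversity_metrics(small_library[:15], seed=0)
        assert 0.0 <= metrics["nn_tanimoto_distance"] <= 1.0

    def test_singleton_errors(self, small_library):
        with pytest.raises(ValueError):
            diversity_metrics(small_library[:1])

    def test_hopkins_near_half_for_uniform_random_fingerprints(self):
        rng = np.random.default_rng(5)
        stubs = [FingerprintStub((rng.random(256) < 0.5).astype(np.uint8))
                 for _ in range(1000)]
        metrics = diversity_metrics(stubs, seed=1)
        assert abs(metrics["hopkins"] - 0.5) < 0.1
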