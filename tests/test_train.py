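"""Training machinery: target transform, pair sampling, losses, full loop."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from rnascreen.model import ModelConfig, ScoreModel
from rnascreen.nn import Adam
from rnascreen.synthetic import make_benchmark
from rnascreen.train import (
    Group,
    GroupedInteractionSet,
    PocketLigandScorer,
    TrainConfig,
    _PairBatch,
    aff_step,
    bce_with_logits,
    compat_step,
    margin_loss,
    quantile_transform,
    quantile_transform_table,
    sample_epoch_pairs,
    train,
)


def brute_force_quantile_oracle(scores, n_bins=50):
    """Independent pair-counting CDF with average ties, quantized and flipped."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    out = np.empty(n)
    for i, s in enumerate(scores):
        n_less = np.sum(scores < s)
        n_eq = np.sum(scores == s)
        avg_rank = n_less + (n_eq + 1) / 2.0
        cdf = (avg_rank - 1) / (n - 1)
        out[i] = np.round((1 - cdf) * (n_bins - 1)) / (n_bins - 1)
    return out


class TestQuantileTransform:
    def test_outputs_within_unit_interval(self):
        rng = np.random.default_rng(0)
        t = quantile_transform(rng.normal(size=200) * 50 - 10)
        assert t.min() >= 0.0 and t.max() <= 1.0

    def test_lower_energy_maps_to_higher_target(self):
        scores = np.array([-9.0, -5.0, -1.0, 3.0])
        t = quantile_transform(scores)
        assert np.all(np.diff(t) < 0)

    def test_matches_rank_cdf_oracle_on_100_distinct_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(np.linspace(-20, 5, 100))
        np.testing.assert_allclose(
            quantile_transform(scores, 50), brute_force_quantile_oracle(scores, 50),
            atol=1e-9,
        )

    def test_ties_share_a_quantile_value(self):
        scores = np.array([-3.0, -3.0, -1.0, 0.0, 0.0])
        t = quantile_transform(scores)
        assert t[0] == t[1] and t[3] == t[4]
        np.testing.assert_allclose(t, brute_force_quantile_oracle(scores), atol=1e-9)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=77)
        np.testing.assert_allclose(
            quantile_transform(scores), quantile_transform(scores * 13.5 - 2.0)
        )

    def test_mean_near_half_for_many_distinct_scores(self):
        rng = np.random.default_rng(3)
        t = quantile_transform(rng.permutation(np.linspace(0, 1, 600)))
        assert abs(t.mean() - 0.5) < 0.02

    def test_errors_on_single_score_and_nan(self):
        with pytest.raises(ValueError):
            quantile_transform([1.0])
        with pytest.raises(ValueError, match="NaN"):
            quantile_transform([1.0, np.nan, 2.0])

    def test_per_pocket_table_application(self):
        df = pd.DataFrame(
            {
                "pocket_id": ["p1"] * 3 + ["p2"] * 3,
                "ligand_id": list("abcabc"),
                "raw_score": [-3.0, -1.0, 2.0, 10.0, 0.0, 5.0],
            }
        )
        out = quantile_transform_table(df, n_bins=50)
        assert out.loc[0, "target"] == 1.0  # best in p1
        assert out.loc[4, "target"] == 1.0  # best in p2


def _toy_dataset(n_groups=4, n_ligs=12, seed=0):
    from rnascreen.synthetic import gen_library, gen_pocket

    lib = gen_library(n_ligs, seed=seed)
    ligands = {l.ligand_id: l for l in lib}
    ids = sorted(ligands)
    groups = []
    for k in range(n_groups):
        actives = ids[2 * k : 2 * k + 2]
        inactives = [i for i in ids if i not in actives]
        groups.append(Group(f"g{k}", gen_pocket(8, seed=seed + k), actives, inactives))
    return GroupedInteractionSet(groups, ligands)


class TestSampleEpochPairs:
    def test_one_active_one_inactive_per_group(self):
        data = _toy_dataset()
        sampled = sample_epoch_pairs(data, seed=0, epoch=0)
        assert len(sampled) == len(data.groups)
        for gid, a, i in sampled:
            g = next(x for x in data.groups if x.group_id == gid)
            assert a in g.actives and i in g.inactives

    def test_deterministic_given_seed_and_epoch(self):
        data = _toy_dataset()
        assert sample_epoch_pairs(data, 5, 3) == sample_epoch_pairs(data, 5, 3)
        assert sample_epoch_pairs(data, 5, 3) != sample_epoch_pairs(data, 5, 4)

    def test_actives_drawn_uniformly_over_epochs(self):
        data = _toy_dataset(n_groups=1, n_ligs=9)
        data.groups[0].actives = data.groups[0].actives + [data.groups[0].inactives.pop()]
        data.groups[0].actives.append(data.groups[0].inactives.pop())
        # group now has 4 actives; check top-3 frequencies over 1000 epochs
        counts: dict = {}
        for epoch in range(1000):
            _, a, _ = sample_epoch_pairs(data, seed=1, epoch=epoch)[0]
            counts[a] = counts.get(a, 0) + 1
        freqs = np.array(list(counts.values())) / 1000
        assert np.all(np.abs(freqs - 1 / len(counts)) < 0.05)

    def test_group_without_actives_errors_with_name(self):
        data = _toy_dataset()
        data.groups[1].actives = []
        with pytest.raises(ValueError, match="g1"):
            sample_epoch_pairs(data, 0, 0)


class TestLosses:
    @pytest.mark.parametrize(
        "wrong,true,alpha,expected",
        [(0.2, 0.9, 0.3, 0.0), (0.9, 0.2, 0.3, 1.0), (0.5, 0.5, 0.0, 0.0)],
    )
    def test_margin_loss_hinge_values(self, wrong, true, alpha, expected):
        assert margin_loss(wrong, true, alpha) == pytest.approx(expected)

    def test_margin_loss_nonnegative_and_alpha_validated(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w, t = rng.normal(size=2)
            assert margin_loss(w, t, 0.2) >= 0.0
        with pytest.raises(ValueError):
            margin_loss(0.0, 0.0, 1.5)

    def test_bce_of_even_logit_is_ln2(self):
        assert bce_with_logits(0.0, 1.0) == pytest.approx(np.log(2))
        assert bce_with_logits(0.0, 0.0) == pytest.approx(np.log(2))

    def test_bce_at_confident_correct_predictions_vanishes(self):
        assert bce_with_logits(30.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert bce_with_logits(-30.0, 0.0) == pytest.approx(0.0, abs=1e-12)


def _small_model(seed=0):
    return ScoreModel(
        config=ModelConfig(n_layers=1, hidden_dim=8, embedding_dim=8, decoder_hidden=8),
        seed=seed,
    )


class TestSteps:
    def test_compat_loss_decreases_over_twenty_steps(self):
        data = _toy_dataset(n_groups=5, n_ligs=14, seed=2)
        model = _small_model()
        cfg = TrainConfig(head_type="compat", alpha=0.2, seed=0)
        opt = Adam(model.params, lr=1e-2)
        pockets = {g.group_id: g.representative for g in data.groups}
        rng = np.random.default_rng(0)
        first = last = None
        for step in range(20):
            sampled = sample_epoch_pairs(data, 0, step)
            gids = [g.group_id for g in data.groups]
            batch = [
                (gid, a, i, gids[(gids.index(gid) + 1) % len(gids)])
                for gid, a, i in sampled
            ]
            losses = compat_step(batch, model, cfg, pockets, data.ligands, opt)
            if first is None:
                first = losses["total"]
            last = losses["total"]
        assert last < first

    def test_compat_step_requires_wrong_pocket(self):
        data = _toy_dataset()
        model = _small_model()
        cfg = TrainConfig(head_type="compat")
        opt = Adam(model.params)
        pockets = {g.group_id: g.representative for g in data.groups}
        batch = [("g0", data.groups[0].actives[0], data.groups[0].inactives[0], None)]
        with pytest.raises(ValueError, match="wrong-pocket"):
            compat_step(batch, model, cfg, pockets, data.ligands, opt)

    def test_aff_step_loss_equals_direct_mse_and_decreases(self):
        data = _toy_dataset(n_groups=3, n_ligs=10, seed=4)
        model = _small_model(1)
        cfg = TrainConfig(head_type="aff")
        opt = Adam(model.params, lr=5e-3)
        pockets = {g.group_id: g.representative for g in data.groups}
        rng = np.random.default_rng(0)
        batch = [
            (g.group_id, lid, float(t))
            for g in data.groups
            for lid, t in zip(sorted(data.ligands), rng.random(4))
        ]
        # independent MSE via one-by-one forward with the *same* weights
        preds = np.array([model.forward(pockets[p], data.ligands[l]) for p, l, _ in batch])
        expected = float(np.mean((preds - [t for _, _, t in batch]) ** 2))
        losses = aff_step(batch, model, cfg, pockets, data.ligands, opt)
        assert losses["l2"] == pytest.approx(expected, abs=1e-10)
        for _ in range(15):
            last = aff_step(batch, model, cfg, pockets, data.ligands, opt)["l2"]
        assert last < losses["l2"]

    def test_aff_step_rejects_unnormalized_targets(self):
        data = _toy_dataset()
        model = _small_model()
        opt = Adam(model.params)
        pockets = {g.group_id: g.representative for g in data.groups}
        batch = [("g0", sorted(data.ligands)[0], -3.2)]
        with pytest.raises(ValueError, match="quantile"):
            aff_step(batch, model, TrainConfig(head_type="aff"), pockets, data.ligands, opt)


class TestTrainLoop:
    def test_fixed_seed_reproducible_history(self, small_benchmark):
        data = small_benchmark.interaction_subset("train")
        runs = []
        for _ in range(2):
            model = _small_model(2)
            cfg = TrainConfig(head_type="compat", epochs=5, seed=7)
            _, hist = train(data, model, cfg)
            runs.append(hist)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_aff_requires_docking_scores(self):
        data = _toy_dataset()
        with pytest.raises(ValueError, match="docking"):
            train(data, _small_model(), TrainConfig(head_type="aff", epochs=1))

    def test_overlapping_labels_rejected(self):
        data = _toy_dataset()
        data.groups[0].inactives.append(data.groups[0].actives[0])
        with pytest.raises(ValueError, match="overlap"):
            data.validate()


class TestEstimator:
    def test_sklearn_params_and_clone(self):
        est = PocketLigandScorer(head="aff", epochs=10, alpha=0.3)
        params = est.get_params()
        assert params["head"] == "aff" and params["alpha"] == 0.3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_validates_input_type(self):
        with pytest.raises(TypeError):
            PocketLigandScorer().fit([1, 2, 3])

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            PocketLigandScorer().predict([])

    def test_fit_predict_shapes_and_determinism(self, small_benchmark):
        data = small_benchmark.interaction_subset("train")
        lib = small_benchmark.library
        est = PocketLigandScorer(
            head="compat", n_layers=1, hidden_dim=8, embedding_dim=8,
            decoder_hidden=8, epochs=8, random_state=0,
        )
        est.fit(data)
        pocket = data.groups[0].representative
        scores = est.score_library(pocket, lib)
        assert scores.shape == (len(lib),)
        pairs = [(pocket, lib[0]), (pocket, lib[1])]
        assert est.predict(pairs).shape == (2,)
        assert np.all((est.predict_proba(pairs) >= 0) & (est.predict_proba(pairs) <= 1))
        est2 = clone(est).fit(data)
        np.testing.assert_array_equal(scores, est2.score_library(pocket, lib))
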