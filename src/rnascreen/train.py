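"""Supervised training of the Compat and Aff scoring heads.

Compat is a native-vs-decoy classifier: a binary cross-entropy loss on
one active and one inactive sampled per binding-site group per epoch
(balancing the heavily skewed pair distribution), plus a specificity
margin loss

    L_m = max( M(G~_F, F) - M(G_F, F) + alpha, 0 )

that pushes a ligand's score with its own pocket above its score with a
wrong pocket G~ drawn from another group.

Aff is a docking-score surrogate: raw docking energies are normalized per
pocket by a rank-based quantile transform with 50 bins onto [0, 1]
(flipped so 1 = best binder) and regressed with an L2 loss.

:class:`PocketLigandScorer` wraps both training loops behind a
scikit-learn style estimator; the module-level functions expose the
individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .model import ModelConfig, ScoreModel
from .nn import Adam, zero_grads_like
from .pockets import PocketGraph

__all__ = [
    "TrainConfig",
    "Group",
    "GroupedInteractionSet",
    "quantile_transform",
    "quantile_transform_table",
    "sample_epoch_pairs",
    "margin_loss",
    "bce_with_logits",
    "compat_step",
    "aff_step",
    "train",
    "PocketLigandScorer",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Group:
    """One similarity group: a representative pocket plus its ligand labels."""

    group_id: str
    representative: PocketGraph
    actives: list[str]
    inactives: list[str]

    def validate(self) -> None:
        overlap = set(self.actives) & set(self.inactives)
        if overlap:
            raise ValueError(
                f"group {self.group_id}: actives and inactives overlap: {sorted(overlap)}"
            )


@dataclass
class GroupedInteractionSet:
    groups: list[Group]
    ligands: dict[str, object]  # ligand_id -> LigandRecord
    docking_scores: pd.DataFrame | None = None  # pocket_id, ligand_id, raw_score

    def validate(self) -> None:
        for g in self.groups:
            g.validate()
            for lid in list(g.actives) + list(g.inactives):
                if lid not in self.ligands:
                    raise ValueError(f"unresolvable ligand id: {lid!r} in group {g.group_id}")


@dataclass
class TrainConfig:
    """Training hyperparameters shared by both heads."""

    head_type: str = "compat"
    alpha: float = 0.2
    margin_weight: float = 1.0
    n_bins: int = 50
    epochs: int = 100
    learning_rate: float = 1e-2
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


# ---------------------------------------------------------------------------
# target transforms and losses


def quantile_transform(scores, n_bins: int = 50) -> np.ndarray:
    """Per-pocket quantile normalization of raw docking energies onto [0, 1].

    Average ranks map the empirical distribution onto [0, 1]; the result is
    quantized onto ``n_bins`` equispaced quantile levels and flipped so
    that lower (better) docking energies receive targets near 1.  Tied raw
    scores share a value; the map is invariant to affine rescaling of the
    raw scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 2:
        raise ValueError("need at least two scores per pocket")
    if np.isnan(scores).any():
        raise ValueError("NaN docking scores")
    n = len(scores)
    cdf = (rankdata(scores, method="average") - 1.0) / (n - 1.0)
    q = 1.0 - cdf  # lower energy -> better binder -> higher target
    return np.round(q * (n_bins - 1)) / (n_bins - 1)


def quantile_transform_table(dock: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Apply :func:`quantile_transform` within each pocket of a score table."""
    out = dock.copy()
    out["target"] = 0.0
    for pid, idx in out.groupby("pocket_id").groups.items():
        out.loc[idx, "target"] = quantile_transform(out.loc[idx, "raw_score"].to_numpy(), n_bins)
    return out


def sample_epoch_pairs(
    data: GroupedInteractionSet, seed: int = 0, epoch: int = 0
) -> list[tuple[str, str, str]]:
    """One (active, inactive) draw per group: (group_id, active_id, inactive_id).

    Deterministic given (seed, epoch); different epochs are independent
    draws, and each active/inactive is drawn uniformly within its group.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch])
    out = []
    for g in data.groups:
        if not g.actives or not g.inactives:
            raise ValueError(f"group {g.group_id} lacks actives or inactives")
        a = g.actives[rng.integers(len(g.actives))]
        i = g.inactives[rng.integers(len(g.inactives))]
        out.append((g.group_id, a, i))
    return out


def margin_loss(score_wrong_pocket: float, score_true_pocket: float, alpha: float) -> float:
    """Hinge on the true-vs-wrong pocket score gap; zero once the gap >= alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return max(score_wrong_pocket - score_true_pocket + alpha, 0.0)


def bce_with_logits(z: float, y: float) -> float:
    """Numerically stable binary cross entropy of a logit against a 0/1 label."""
    return float(np.logaddexp(0.0, z) - y * z)


# ---------------------------------------------------------------------------
# batched forward/backward over pocket-ligand pairs


class _PairBatch:
    """Shared-embedding forward/backward over a set of (pocket, ligand) pairs."""

    def __init__(self, model: ScoreModel, pockets: dict[str, PocketGraph], ligands: dict):
        self.model = model
        self.pockets = pockets
        self.ligands = ligands

    def forward(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        m = self.model
        self._pairs = pairs
        self._p_ids = sorted({p for p, _ in pairs})
        self._l_ids = sorted({l for _, l in pairs})
        self._p_caches, self._l_caches = {}, {}
        self._p_emb, self._l_emb = {}, {}
        for pid in self._p_ids:
            cache: list = []
            gt = m.pocket_to_tensor(self.pockets[pid])
            self._p_emb[pid] = m.pocket_encoder.embed(gt, cache)
            self._p_caches[pid] = (gt, cache)
        for lid in self._l_ids:
            cache = []
            gt = m.ligand_to_tensor(self.ligands[lid])
            self._l_emb[lid] = m.ligand_encoder.embed(gt, cache)
            self._l_caches[lid] = (gt, cache)
        U = np.array(
            [np.concatenate([self._p_emb[p], self._l_emb[l]]) for p, l in pairs]
        )
        self._dec_cache: list = []
        return m.decoder.forward(U, self._dec_cache)

    def backward(self, d_scores: np.ndarray) -> dict[str, np.ndarray]:
        m = self.model
        gd = zero_grads_like(m.decoder.params)
        dU = m.decoder.backward(self._dec_cache[0], d_scores, gd)
        d = m.config.embedding_dim
        dp = {pid: np.zeros(d) for pid in self._p_ids}
        dl = {lid: np.zeros(d) for lid in self._l_ids}
        for row, (pid, lid) in enumerate(self._pairs):
            dp[pid] += dU[row, :d]
            dl[lid] += dU[row, d:]
        gp = zero_grads_like(m.pocket_encoder.params)
        gl = zero_grads_like(m.ligand_encoder.params)
        for pid in self._p_ids:
            gt, cache = self._p_caches[pid]
            m.pocket_encoder.backward(gt, cache, dp[pid], gp)
        for lid in self._l_ids:
            gt, cache = self._l_caches[lid]
            m.ligand_encoder.backward(gt, cache, dl[lid], gl)
        flat = {f"penc.{k}": v for k, v in gp.items()}
        flat.update({f"lenc.{k}": v for k, v in gl.items()})
        flat.update({f"dec.{k}": v for k, v in gd.items()})
        return flat


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def compat_step(
    batch: list[tuple[str, str, str, str]],
    model: ScoreModel,
    cfg: TrainConfig,
    pockets: dict[str, PocketGraph],
    ligands: dict,
    optimizer: Adam,
) -> dict[str, float]:
    """One gradient step of the Compat objective.

    ``batch`` rows are (pocket_id, active_id, inactive_id, wrong_pocket_id).
    Total loss per group: BCE(M(G, a), 1) + BCE(M(G, i), 0) +
    margin_weight * L_m(M(G~, a), M(G, a)).  Returns the separately logged
    loss components.
    """
    for row in batch:
        if row[3] is None:
            raise ValueError(f"missing wrong-pocket draw for group pocket {row[0]}")
    pairs = []
    for pid, a, i, wrong in batch:
        pairs.extend([(pid, a), (pid, i), (wrong, a)])
    pb = _PairBatch(model, pockets, ligands)
    scores = pb.forward(pairs)
    n = len(batch)
    d_scores = np.zeros_like(scores)
    bce_total, margin_total = 0.0, 0.0
    for k in range(n):
        z_pos, z_neg, z_wrong = scores[3 * k], scores[3 * k + 1], scores[3 * k + 2]
        bce_total += bce_with_logits(z_pos, 1.0) + bce_with_logits(z_neg, 0.0)
        d_scores[3 * k] += _sigmoid(z_pos) - 1.0
        d_scores[3 * k + 1] += _sigmoid(z_neg)
        m = margin_loss(z_wrong, z_pos, cfg.alpha)
        margin_total += m
        if m > 0:
            d_scores[3 * k + 2] += cfg.margin_weight
            d_scores[3 * k] -= cfg.margin_weight
    d_scores /= n
    grads = pb.backward(d_scores)
    optimizer.step(model.params, grads)
    return {"bce": bce_total / n, "margin": margin_total / n,
            "total": (bce_total + cfg.margin_weight * margin_total) / n}


def aff_step(
    batch: list[tuple[str, str, float]],
    model: ScoreModel,
    cfg: TrainConfig,
    pockets: dict[str, PocketGraph],
    ligands: dict,
    optimizer: Adam,
) -> dict[str, float]:
    """One L2 regression step on quantile-normalized docking targets.

    ``batch`` rows are (pocket_id, ligand_id, target) with targets already
    in [0, 1] (enforced: an out-of-range target signals a missing quantile
    transform).
    """
    targets = np.array([t for _, _, t in batch], dtype=float)
    if ((targets < 0) | (targets > 1)).any():
        raise ValueError("targets outside [0, 1]; apply quantile_transform first")
    pairs = [(p, l) for p, l, _ in batch]
    pb = _PairBatch(model, pockets, ligands)
    preds = pb.forward(pairs)
    resid = preds - targets
    loss = float(np.mean(resid**2))
    grads = pb.backward(2.0 * resid / len(batch))
    optimizer.step(model.params, grads)
    return {"l2": loss, "total": loss}


# ---------------------------------------------------------------------------
# full training loop


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .screen import auroc

    return auroc(scores, labels)


def train(
    data: GroupedInteractionSet,
    model: ScoreModel,
    cfg: TrainConfig,
) -> tuple[ScoreModel, pd.DataFrame]:
    """Train a scoring head end to end; returns the model and its history.

    A seeded ``validation_fraction`` of the groups is held aside for
    checkpointing (best validation AuROC for Compat, best validation L2
    for Aff); the remaining groups are the training set.  Reproducible
    given ``cfg.seed``; NaN losses abort with a diagnostic.
    """
    data.validate()
    rng = np.random.default_rng(cfg.seed)
    pockets = {g.group_id: g.representative for g in data.groups}
    order = rng.permutation(len(data.groups))
    n_val = max(1, int(round(cfg.validation_fraction * len(data.groups)))) if len(data.groups) > 2 else 0
    val_groups = [data.groups[i] for i in order[:n_val]]
    train_groups = [data.groups[i] for i in order[n_val:]]
    train_data = GroupedInteractionSet(train_groups, data.ligands, data.docking_scores)
    opt = Adam(model.params, lr=cfg.learning_rate)
    history = []

    aff_train_batch = aff_val_batch = None
    if cfg.head_type == "aff":
        if data.docking_scores is None:
            raise ValueError("aff training requires docking scores")
        table = quantile_transform_table(data.docking_scores, cfg.n_bins)
        train_ids = {g.group_id for g in train_groups}
        val_ids = {g.group_id for g in val_groups}
        rows = [tuple(r) for r in table[["pocket_id", "ligand_id", "target"]].itertuples(index=False)]
        aff_train_batch = [r for r in rows if r[0] in train_ids]
        aff_val_batch = [r for r in rows if r[0] in val_ids]
        if not aff_train_batch:
            raise ValueError("no docking scores for the training groups")

    best_metric = -np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    for epoch in range(cfg.epochs):
        if cfg.head_type == "compat":
            sampled = sample_epoch_pairs(train_data, cfg.seed, epoch)
            epoch_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, epoch, 7])
            batch = []
            gids = [g.group_id for g in train_groups]
            for gid, a, i in sampled:
                others = [x for x in gids if x != gid]
                wrong = others[epoch_rng.integers(len(others))] if others else None
                batch.append((gid, a, i, wrong))
            losses = compat_step(batch, model, cfg, pockets, data.ligands, opt)
        else:
            losses = aff_step(aff_train_batch, model, cfg, pockets, data.ligands, opt)
        if not np.isfinite(losses["total"]):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")

        val_metric = np.nan
        if val_groups:
            if cfg.head_type == "compat":
                per_group = []
                for g in val_groups:
                    lids = list(g.actives) + list(g.inactives)
                    scores = model.score_library(g.representative, [data.ligands[l] for l in lids])
                    labels = np.array([1] * len(g.actives) + [0] * len(g.inactives))
                    if labels.any() and not labels.all():
                        per_group.append(_auroc(scores, labels))
                val_metric = float(np.mean(per_group)) if per_group else np.nan
            else:
                if aff_val_batch:
                    pb = _PairBatch(model, pockets, data.ligands)
                    preds = pb.forward([(p, l) for p, l, _ in aff_val_batch])
                    targets = np.array([t for _, _, t in aff_val_batch])
                    val_metric = -float(np.mean((preds - targets) ** 2))
        row = {"epoch": epoch, **losses, "val_metric": val_metric}
        history.append(row)
        metric_now = val_metric if np.isfinite(val_metric) else -losses["total"]
        if metric_now >= best_metric:
            best_metric = metric_now
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.set_params_array(best_params)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# estimator


class PocketLigandScorer(BaseEstimator):
    """Scikit-learn style estimator around the pocket-ligand scoring network.

    Parameters mirror :class:`TrainConfig` and :class:`ModelConfig`.  After
    ``fit`` the trained network is available as ``model_`` and the training
    log as ``history_``.

    Examples
    --------
    >>> scorer = PocketLigandScorer(head="compat", epochs=30, random_state=0)
    >>> scorer.fit(interactions)                      # doctest: +SKIP
    >>> scores = scorer.score_library(pocket, ligands)  # doctest: +SKIP
    """

    def __init__(
        self,
        head: str = "compat",
        n_layers: int = 3,
        hidden_dim: int = 64,
        embedding_dim: int = 64,
        decoder_hidden: int = 64,
        alpha: float = 0.2,
        margin_weight: float = 1.0,
        n_bins: int = 50,
        epochs: int = 100,
        learning_rate: float = 1e-2,
        validation_fraction: float = 0.1,
        random_state: int = 0,
        pretrained_pocket_encoder=None,
    ) -> None:
        self.head = head
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.embedding_dim = embedding_dim
        self.decoder_hidden = decoder_hidden
        self.alpha = alpha
        self.margin_weight = margin_weight
        self.n_bins = n_bins
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.pretrained_pocket_encoder = pretrained_pocket_encoder

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            head_type=self.head,
            alpha=self.alpha,
            margin_weight=self.margin_weight,
            n_bins=self.n_bins,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )

    def fit(self, data: GroupedInteractionSet, y=None) -> "PocketLigandScorer":
        if not isinstance(data, GroupedInteractionSet):
            raise TypeError("fit expects a GroupedInteractionSet")
        if not data.groups:
            raise ValueError("no groups to train on")
        rep = data.groups[0].representative
        model = ScoreModel(
            head_type=self.head,
            relation_vocab=rep.relation_vocab,
            lm_dim=rep.lm_dim,
            config=ModelConfig(
                n_layers=self.n_layers,
                hidden_dim=self.hidden_dim,
                embedding_dim=self.embedding_dim,
                decoder_hidden=self.decoder_hidden,
            ),
            seed=self.random_state,
        )
        if self.pretrained_pocket_encoder is not None:
            for k, v in self.pretrained_pocket_encoder.params.items():
                model.pocket_encoder.params[k] = v.copy()
        self.model_, self.history_ = train(data, model, self._train_config())
        self.relation_vocab_ = model.relation_vocab
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict(self, X: list[tuple[PocketGraph, object]]) -> np.ndarray:
        """Scores for a list of (pocket, ligand) pairs (higher = better)."""
        self._check_fitted()
        return np.array([self.model_.forward(g, l) for g, l in X])

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        if self.head != "compat":
            raise ValueError("predict_proba is only defined for the compat head")
        return _sigmoid(self.predict(X))

    def score_library(self, pocket: PocketGraph, ligands: list) -> np.ndarray:
        self._check_fitted()
        return self.model_.score_library(pocket, ligands)
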