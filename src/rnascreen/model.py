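"""The pocket-ligand scoring model M(G, F).

A binding-site graph G is embedded by a relational graph-convolution
encoder f, the ligand molecular graph F by a plain GCN encoder g (the
single-relation special case of the same layer), and a feed-forward
decoder h maps the concatenated embeddings to a real score:

    M(G, F) = h( f(G) (+) g(F) )

The ``compat`` head is trained as a native-vs-decoy classifier and exposes
a logistic probability at inference; the ``aff`` head regresses per-pocket
quantile-normalized docking scores.  In both cases higher scores mean
better predicted binding.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    MLP,
    Adam,
    GraphTensor,
    RGCNEncoder,
    ligand_input_dim,
    ligand_tensor,
    pocket_tensor,
    zero_grads_like,
)
from .pockets import DEFAULT_RELATION_VOCAB, PocketGraph

__all__ = ["ModelConfig", "ScoreModel", "encode_pocket", "encode_ligand", "model_forward"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: 3 rGCN layers, width 64)."""

    n_layers: int = 3
    hidden_dim: int = 64
    embedding_dim: int = 64
    decoder_hidden: int = 64
    activation: str = "relu"

    def encoder_dims(self) -> list[int]:
        return [self.hidden_dim] * (self.n_layers - 1) + [self.embedding_dim]


class ScoreModel:
    """Pocket encoder + ligand encoder + decoder with a named head.

    ``head_type`` is ``"compat"`` (classifier; ``predict_proba`` applies the
    logistic map to the raw score) or ``"aff"`` (docking-surrogate
    regressor).  The relation vocabulary and input feature dims are fixed at
    construction and stored in checkpoints so weights and graphs agree.
    """

    def __init__(
        self,
        head_type: str = "compat",
        relation_vocab=DEFAULT_RELATION_VOCAB,
        lm_dim: int = 0,
        config: ModelConfig | None = None,
        seed: int = 0,
    ) -> None:
        if head_type not in ("compat", "aff"):
            raise ValueError(f"unknown head_type: {head_type!r}")
        self.head_type = head_type
        self.relation_vocab = tuple(relation_vocab)
        self.lm_dim = int(lm_dim)
        self.config = config or ModelConfig()
        self.seed = int(seed)
        pocket_in = 5 + self.lm_dim
        dims = self.config.encoder_dims()
        self.pocket_encoder = RGCNEncoder(
            len(self.relation_vocab), pocket_in, dims, seed=seed, activation=self.config.activation
        )
        self.ligand_encoder = RGCNEncoder(
            1, ligand_input_dim(), dims, seed=seed + 1, activation=self.config.activation
        )
        self.decoder = MLP(2 * self.config.embedding_dim, self.config.decoder_hidden, seed=seed + 2)
        self._pocket_cache: dict[str, GraphTensor] = {}
        self._ligand_cache: dict[str, GraphTensor] = {}

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, comp in (
            ("penc", self.pocket_encoder),
            ("lenc", self.ligand_encoder),
            ("dec", self.decoder),
        ):
            for k, v in comp.params.items():
                out[f"{prefix}.{k}"] = v
        return out

    def set_params_array(self, flat: dict[str, np.ndarray]) -> None:
        for prefix, comp in (
            ("penc", self.pocket_encoder),
            ("lenc", self.ligand_encoder),
            ("dec", self.decoder),
        ):
            for k in comp.params:
                comp.params[k] = np.array(flat[f"{prefix}.{k}"])

    def zero_grads(self) -> dict[str, np.ndarray]:
        return zero_grads_like(self.params)

    # -- tensors ------------------------------------------------------------

    def pocket_to_tensor(self, g: PocketGraph) -> GraphTensor:
        if g.relation_vocab != self.relation_vocab:
            raise ValueError("pocket relation vocabulary does not match the model")
        expected_lm = self.lm_dim
        if expected_lm > 0 and g.lm_dim != expected_lm:
            raise ValueError(
                f"pocket lm feature dim {g.lm_dim} != model lm_dim {expected_lm}"
            )
        key = g.pocket_id
        if key not in self._pocket_cache or self._pocket_cache[key].node_order != g.node_ids:
            self._pocket_cache[key] = pocket_tensor(g, use_lm=expected_lm > 0)
        return self._pocket_cache[key]

    def ligand_to_tensor(self, lig) -> GraphTensor:
        key = lig.ligand_id
        if key not in self._ligand_cache:
            self._ligand_cache[key] = ligand_tensor(lig)
        return self._ligand_cache[key]

    # -- inference ----------------------------------------------------------

    def encode_pocket(self, g: PocketGraph) -> np.ndarray:
        return self.pocket_encoder.embed(self.pocket_to_tensor(g))

    def encode_ligand(self, lig) -> np.ndarray:
        return self.ligand_encoder.embed(self.ligand_to_tensor(lig))

    def forward(self, g: PocketGraph, lig) -> float:
        """M(G, F): scalar score for one pocket-ligand pair."""
        u = np.concatenate([self.encode_pocket(g), self.encode_ligand(lig)])
        return float(self.decoder.forward(u[None, :])[0])

    def predict_proba(self, g: PocketGraph, lig) -> float:
        if self.head_type != "compat":
            raise ValueError("probabilities are only defined for the compat head")
        return float(1.0 / (1.0 + np.exp(-self.forward(g, lig))))

    def score_library(self, g: PocketGraph, ligands: list) -> np.ndarray:
        """Score one pocket against a library (batched over the decoder)."""
        ep = self.encode_pocket(g)
        E = np.array([self.ligand_encoder.embed(self.ligand_to_tensor(l)) for l in ligands])
        U = np.hstack([np.repeat(ep[None, :], len(ligands), axis=0), E])
        return self.decoder.forward(U)

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights + architecture header."""
        header = {
            "head_type": self.head_type,
            "relation_vocab": list(self.relation_vocab),
            "lm_dim": self.lm_dim,
            "seed": self.seed,
            "config": {
                "n_layers": self.config.n_layers,
                "hidden_dim": self.config.hidden_dim,
                "embedding_dim": self.config.embedding_dim,
                "decoder_hidden": self.config.decoder_hidden,
                "activation": self.config.activation,
            },
        }
        arrays = {k.replace(".", "__"): v for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                **arrays,
            )

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            arrays = {
                k.replace("__", "."): np.array(v)
                for k, v in data.items()
                if k != "__header__"
            }
        model = cls(
            head_type=header["head_type"],
            relation_vocab=tuple(header["relation_vocab"]),
            lm_dim=header["lm_dim"],
            config=ModelConfig(**header["config"]),
            seed=header["seed"],
        )
        model.set_params_array(arrays)
        return model


# -- thin functional surface --------------------------------------------------


def encode_pocket(g: PocketGraph, model: ScoreModel) -> np.ndarray:
    """Graph-level embedding of a binding site (deterministic given weights)."""
    return model.encode_pocket(g)


def encode_ligand(lig, model: ScoreModel) -> np.ndarray:
    return model.encode_ligand(lig)


def model_forward(g: PocketGraph, lig, model: ScoreModel) -> float:
    return model.forward(g, lig)
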