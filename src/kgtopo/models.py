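"""Shallow knowledge-graph-embedding models: TransE, DistMult, RotatE, TripleRE.

Each model assigns a low-dimensional vector to every entity and relation and
scores a triple (h, r, t) by combining them; higher scores mean more
plausible. The scoring functions (with ``e_h``, ``e_r``, ``e_t`` the
embeddings):

* TransE     s = -|| e_h + e_r - e_t ||_p
* DistMult   s = sum_i e_h,i * e_r,i * e_t,i
* RotatE     s = -sum_j | e_h,j * e_r,j - e_t,j |  with complex entity
  embeddings and unit-modulus relation rotations (parameterised by phases,
  so the modulus constraint holds by construction); the distance is the sum
  of component-wise complex moduli
* TripleRE   s = -|| e_h o r_head - e_t o r_tail + r_mid ||_p

These forms differ in which edge patterns they can represent: DistMult is
symmetric by construction (s(h,r,t) = s(t,r,h) exactly), TransE cannot model
symmetry at all (e_r = 0 would be needed), RotatE and TripleRE can express
symmetry, inversion and composition.

Training minimises either a self-adversarial negative-sampling loss or a
margin-ranking loss over uniformly corrupted triples, by mini-batch gradient
descent with closed-form gradients (the scorers are simple enough that no
autodiff is needed). All randomness flows from a single seed; two runs with
the same seed produce identical embeddings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .graph import KnowledgeGraph

SCORERS = ("transe", "distmult", "rotate", "triplere")


class TrainingDiverged(RuntimeError):
    """Non-finite loss encountered during training."""


@dataclass
class ModelConfig:
    """Hyperparameters for one scoring function.

    ``embedding_dim`` is the number of real components per entity (RotatE
    uses ``embedding_dim // 2`` complex components). ``margin`` is the gamma
    offset of both losses; ``norm`` selects L1/L2 for the distance-based
    scorers. ``corruption`` chooses which side of a positive is replaced
    when sampling negatives.
    """

    scoring: str = "distmult"
    embedding_dim: int = 64
    norm: int = 1
    margin: float = 9.0
    learning_rate: float = 0.05
    epochs: int = 50
    batch_size: int = 256
    num_negatives: int = 64
    loss: str = "self_adversarial"  # or "margin"
    adversarial_temperature: float = 1.0
    corruption: str = "both"  # head | tail | both
    optimizer: str = "adagrad"  # or "sgd"
    seed: int = 0

    def validate(self) -> None:
        if self.scoring not in SCORERS:
            raise ValueError(f"unknown scoring function {self.scoring!r}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.scoring == "rotate" and self.embedding_dim % 2:
            raise ValueError("rotate needs an even embedding_dim (pairs of reals)")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 or 2")
        if self.loss not in ("self_adversarial", "margin"):
            raise ValueError("loss must be 'self_adversarial' or 'margin'")
        if self.corruption not in ("head", "tail", "both"):
            raise ValueError("corruption must be head, tail or both")


_EPS = 1e-12


class EmbeddingSet:
    """Entity and relation embedding tables for one scoring function.

    Parameters are held in ``self.params`` (real float64 arrays; RotatE
    entities are stored as interleaved re/im pairs and viewed as complex).
    """

    def __init__(self, config: ModelConfig, n_entities: int, n_relations: int,
                 rng: np.random.Generator | None = None):
        config.validate()
        self.config = config
        self.n_entities = n_entities
        self.n_relations = n_relations
        self.training_log: list[dict] = []
        rng = rng or np.random.default_rng(config.seed)
        d, g = config.embedding_dim, config.margin
        bound = g / d
        p: dict[str, np.ndarray] = {}
        if config.scoring == "transe":
            p["entity"] = rng.uniform(-bound, bound, (n_entities, d))
            p["relation"] = rng.uniform(-bound, bound, (n_relations, d))
        elif config.scoring == "distmult":
            p["entity"] = rng.normal(0.0, 0.1, (n_entities, d))
            p["relation"] = rng.normal(0.0, 0.1, (n_relations, d))
        elif config.scoring == "rotate":
            p["entity"] = rng.uniform(-bound, bound, (n_entities, d))
            p["phase"] = rng.uniform(0.0, 2 * np.pi, (n_relations, d // 2))
        else:  # triplere
            p["entity"] = rng.uniform(-bound, bound, (n_entities, d))
            for part in ("rel_head", "rel_tail", "rel_mid"):
                p[part] = rng.uniform(-bound, bound, (n_relations, d))
        self.params = p

    # -- helpers ------------------------------------------------------------

    def _entity_complex(self) -> np.ndarray:
        return np.ascontiguousarray(self.params["entity"]).view(np.complex128)

    def _check_ids(self, h, r, t) -> None:
        for name, arr, n in (("entity", h, self.n_entities), ("relation", r, self.n_relations),
                             ("entity", t, self.n_entities)):
            a = np.asarray(arr)
            if a.size and (a.min() < 0 or a.max() >= n):
                raise IndexError(f"{name} id out of range")

    def relation_rotations(self) -> np.ndarray:
        """Unit-modulus complex rotation coefficients (RotatE only)."""
        return np.exp(1j * self.params["phase"])

    # -- scoring ------------------------------------------------------------

    def score(self, h, r, t) -> np.ndarray:
        """Scores for id arrays (or scalars) h, r, t; higher = more plausible."""
        scalar = np.isscalar(h) and np.isscalar(r) and np.isscalar(t)
        h = np.atleast_1d(np.asarray(h, dtype=np.int64))
        r = np.atleast_1d(np.asarray(r, dtype=np.int64))
        t = np.atleast_1d(np.asarray(t, dtype=np.int64))
        self._check_ids(h, r, t)
        s = self._score_idx(h, r, t)
        return float(s[0]) if scalar else s

    def _score_idx(self, h, r, t) -> np.ndarray:
        c = self.config
        p = self.params
        if c.scoring == "transe":
            u = p["entity"][h] + p["relation"][r] - p["entity"][t]
            return -_pnorm(u, c.norm)
        if c.scoring == "distmult":
            # (e_h * e_t) first, so s(h,r,t) == s(t,r,h) holds bitwise
            return ((p["entity"][h] * p["entity"][t]) * p["relation"][r]).sum(axis=1)
        if c.scoring == "rotate":
            E = self._entity_complex()
            u = E[h] * np.exp(1j * p["phase"][r]) - E[t]
            return -np.abs(u).sum(axis=1)
        u = (p["entity"][h] * p["rel_head"][r]
             - p["entity"][t] * p["rel_tail"][r] + p["rel_mid"][r])
        return -_pnorm(u, c.norm)

    def score_tails(self, h: int, r: int, candidates: np.ndarray | None = None) -> np.ndarray:
        """Scores of (h, r, c) for every candidate tail c, batched."""
        if candidates is None:
            candidates = np.arange(self.n_entities)
        candidates = np.asarray(candidates, dtype=np.int64)
        self._check_ids(np.asarray([h]), np.asarray([r]), candidates)
        c = self.config
        p = self.params
        if c.scoring == "transe":
            q = p["entity"][h] + p["relation"][r]
            return -_pnorm(q[None, :] - p["entity"][candidates], c.norm)
        if c.scoring == "distmult":
            q = p["entity"][h] * p["relation"][r]
            return p["entity"][candidates] @ q
        if c.scoring == "rotate":
            E = self._entity_complex()
            q = E[h] * np.exp(1j * p["phase"][r])
            return -np.abs(q[None, :] - E[candidates]).sum(axis=1)
        q = p["entity"][h] * p["rel_head"][r] + p["rel_mid"][r]
        u = q[None, :] - p["entity"][candidates] * p["rel_tail"][r]
        return -_pnorm(u, c.norm)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "embeddings.npz", **self.params)
        meta = {
            "config": asdict(self.config),
            "n_entities": self.n_entities,
            "n_relations": self.n_relations,
            "training_log": self.training_log,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingSet":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(ModelConfig(**meta["config"]), meta["n_entities"], meta["n_relations"])
        with np.load(directory / "embeddings.npz") as data:
            model.params = {k: data[k] for k in data.files}
        model.training_log = meta["training_log"]
        return model


def _pnorm(u: np.ndarray, p: int) -> np.ndarray:
    if p == 1:
        return np.abs(u).sum(axis=1)
    return np.sqrt((u * u).sum(axis=1) + 0.0)


def _pnorm_grad(u: np.ndarray, p: int) -> np.ndarray:
    """d||u||_p / du (subgradient 0 at kinks)."""
    if p == 1:
        return np.sign(u)
    nrm = np.sqrt((u * u).sum(axis=1, keepdims=True))
    return u / np.maximum(nrm, _EPS)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _accumulate_gradients(model: EmbeddingSet, h, r, t, dl, grads: dict[str, np.ndarray]) -> None:
    """Add dL/dparam for triples (h, r, t) with upstream dL/ds = dl."""
    c = model.config
    p = model.params
    dl1 = dl[:, None]
    if c.scoring == "transe":
        u = p["entity"][h] + p["relation"][r] - p["entity"][t]
        du = -_pnorm_grad(u, c.norm) * dl1  # ds/du = -grad(norm)
        np.add.at(grads["entity"], h, du)
        np.add.at(grads["relation"], r, du)
        np.add.at(grads["entity"], t, -du)
    elif c.scoring == "distmult":
        eh, er, et = p["entity"][h], p["relation"][r], p["entity"][t]
        np.add.at(grads["entity"], h, dl1 * er * et)
        np.add.at(grads["relation"], r, dl1 * eh * et)
        np.add.at(grads["entity"], t, dl1 * eh * er)
    elif c.scoring == "rotate":
        E = model._entity_complex()
        rot = np.exp(1j * p["phase"][r])
        eh = E[h]
        u = eh * rot - E[t]
        mod = np.abs(u)
        gu = (-u / np.maximum(mod, _EPS)) * dl1  # complex dL/du, modulus-sum distance
        ge = grads["entity"].view(np.complex128)
        np.add.at(ge, h, gu * np.conj(rot))
        np.add.at(ge, t, -gu)
        np.add.at(grads["phase"], r, (np.conj(gu) * (1j * rot * eh)).real)
    else:  # triplere
        eh, et = p["entity"][h], p["entity"][t]
        rh, rt, rm = p["rel_head"][r], p["rel_tail"][r], p["rel_mid"][r]
        u = eh * rh - et * rt + rm
        du = -_pnorm_grad(u, c.norm) * dl1
        np.add.at(grads["entity"], h, du * rh)
        np.add.at(grads["rel_head"], r, du * eh)
        np.add.at(grads["entity"], t, -du * rt)
        np.add.at(grads["rel_tail"], r, -du * et)
        np.add.at(grads["rel_mid"], r, du)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def train(train_graph: KnowledgeGraph, config: ModelConfig) -> EmbeddingSet:
    """Fit an EmbeddingSet on the graph's triples by mini-batch descent.

    If the graph carries split tags only the train split is used. Negatives
    are uniform entity replacements on the configured corruption side. The
    default loss is the self-adversarial one: negatives are reweighted by a
    softmax of their own scores (treated as constants), so the optimiser
    concentrates on the hardest corruptions. Raises :class:`TrainingDiverged`
    on a non-finite loss.
    """
    config.validate()
    triples = train_graph.split_triples("train") if train_graph.split is not None \
        else train_graph.triples
    if len(triples) == 0:
        raise ValueError("training graph is empty")
    rng = np.random.default_rng(config.seed)
    model = EmbeddingSet(config, train_graph.n_entities, train_graph.n_relations, rng)
    n, K, gamma = len(triples), config.num_negatives, config.margin
    accum = {k: np.zeros_like(v) for k, v in model.params.items()}

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = triples[order[start : start + config.batch_size]]
            B = len(batch)
            h, r, t = batch[:, 0], batch[:, 1], batch[:, 2]
            # corrupt one side per negative
            cand = rng.integers(0, model.n_entities, size=(B, K))
            if config.corruption == "both":
                corrupt_head = rng.random((B, K)) < 0.5
            else:
                corrupt_head = np.full((B, K), config.corruption == "head")
            h_neg = np.where(corrupt_head, cand, h[:, None])
            t_neg = np.where(corrupt_head, t[:, None], cand)
            r_neg = np.broadcast_to(r[:, None], (B, K))

            s_pos = model._score_idx(h, r, t)
            s_neg = model._score_idx(h_neg.ravel(), r_neg.ravel(), t_neg.ravel()).reshape(B, K)

            if config.loss == "self_adversarial":
                logits = config.adversarial_temperature * s_neg
                logits -= logits.max(axis=1, keepdims=True)
                w = np.exp(logits)
                w /= w.sum(axis=1, keepdims=True)
                loss = _softplus(-(gamma + s_pos)).mean() + \
                    (w * _softplus(gamma + s_neg)).sum(axis=1).mean()
                dl_pos = -_sigmoid(-(gamma + s_pos)) / B
                dl_neg = w * _sigmoid(gamma + s_neg) / B
            else:  # margin ranking
                viol = np.maximum(0.0, gamma - s_pos[:, None] + s_neg)
                loss = viol.mean()
                active = (viol > 0).astype(float)
                dl_pos = -active.sum(axis=1) / (B * K)
                dl_neg = active / (B * K)

            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: lower the learning rate"
                )
            epoch_loss += float(loss)
            n_batches += 1

            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            _accumulate_gradients(model, h, r, t, dl_pos, grads)
            _accumulate_gradients(model, h_neg.ravel(), r_neg.ravel(), t_neg.ravel(),
                                  dl_neg.ravel(), grads)
            lr = config.learning_rate
            for k, g in grads.items():
                if config.optimizer == "adagrad":
                    accum[k] += g * g
                    model.params[k] -= lr * g / (np.sqrt(accum[k]) + 1e-10)
                else:
                    model.params[k] -= lr * g
        model.training_log.append({"epoch": epoch, "mean_loss": epoch_loss / n_batches})
    return model
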