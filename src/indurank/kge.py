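"""Knowledge-graph embeddings of the projected ontology graph.

Four scoring functions over triples (h, r, t), higher = more plausible:

* TransE   f = -||h + r - t||_p                      (p in {1, 2})
* TransH   f = -||(h - w_r'h w_r) + r - (t - w_r't w_r)||_2^2
* TransD   f = -||(w_r w_h' + I)h + r - (w_r w_t' + I)t||_2^2
* ConvKB   f = [v_1;...;v_tau] . w,   v_i = ReLU(omega_i * [h, r, t] + b)

where TransH projects entities onto a relation-specific hyperplane with
unit normal w_r, TransD projects via entity-specific vectors w_h, w_t
and a relation vector w_r (I is the rectangular identity when the
relation space dimension k differs from the entity dimension d), and
ConvKB convolves width-3 filters omega_i down the rows of the stacked
d x 3 matrix [h, r, t].

Training minimizes a margin ranking loss max(0, gamma - f(pos) + f(neg))
for the translational models and a soft-margin logistic loss for ConvKB,
with uniformly corrupted negatives, by mini-batch Adam (or plain SGD).
Gradients are written out analytically; everything is plain numpy, which
is entirely adequate at the graph sizes this package targets and keeps
runs bit-reproducible under a fixed seed in single-threaded mode.

ConvKB is conventionally warm-started from pretrained translational
embeddings: from TransE (plain ConvKB) or from TransD ("ConvKB-D").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .graph import LabeledGraph

MODELS = ("transe", "transh", "transd", "convkb", "convkb_d")

# hyperparameter search space used at full data scale
DEFAULT_GRID = {
    "dim": [100, 200, 300, 400],
    "batch_size": [1024, 2048, 4096, 8192],
    "learning_rate": [0.0001, 0.001, 0.01],
    "n_filters": [100, 200],
}

Triple = tuple[str, str, str]


@dataclass
class EmbeddingSet:
    """Trained embedding tables plus model metadata."""

    model: str
    entity_index: dict[str, int]
    relation_index: dict[str, int]
    entity_vectors: np.ndarray                      # (n_e, d)
    relation_vectors: np.ndarray                    # (n_r, d) or (n_r, k)
    relation_normals: np.ndarray | None = None      # TransH w_r / TransD w_r
    entity_projections: np.ndarray | None = None    # TransD w_h/w_t
    conv_filters: np.ndarray | None = None          # (tau, 3)
    conv_weight: np.ndarray | None = None           # (tau * d,)
    conv_bias: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        need_normals = self.model in ("transh", "transd")
        if need_normals and self.relation_normals is None:
            raise ValueError(f"{self.model} requires relation_normals")
        if self.model == "transd" and self.entity_projections is None:
            raise ValueError("transd requires entity_projections")
        if self.model in ("convkb", "convkb_d") and (
            self.conv_filters is None or self.conv_weight is None or self.conv_bias is None
        ):
            raise ValueError(f"{self.model} requires conv filters, weight and bias")

    @property
    def dim(self) -> int:
        return self.entity_vectors.shape[1]

    def has_entity(self, term: str) -> bool:
        return term in self.entity_index

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.entity_vectors[self.entity_index[term]]
        except KeyError:
            raise UnknownEntityError(term) from None

    def vectors(self, terms: Sequence[str]) -> np.ndarray:
        try:
            return self.entity_vectors[[self.entity_index[t] for t in terms]]
        except KeyError as exc:
            raise UnknownEntityError(exc.args[0]) from None


class UnknownEntityError(KeyError):
    """Entity absent from the embedding vocabulary (the transductive
    failure mode: a never-embedded disease cannot be scored directly)."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"entity {term!r} is not in the embedding vocabulary")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _rect_identity_apply(x: np.ndarray, k: int) -> np.ndarray:
    """Apply the d->k rectangular identity to rows of x (..., d)."""
    d = x.shape[-1]
    if k == d:
        return x
    if k < d:
        return x[..., :k]
    pad = np.zeros(x.shape[:-1] + (k - d,), dtype=x.dtype)
    return np.concatenate([x, pad], axis=-1)


def _rect_identity_applyT(y: np.ndarray, d: int) -> np.ndarray:
    """Apply the transpose (k->d) of the rectangular identity."""
    return _rect_identity_apply(y, d)


def _translation_error(emb: EmbeddingSet, hi, ri, ti) -> np.ndarray:
    model = emb.model
    E, R = emb.entity_vectors, emb.relation_vectors
    if model == "transe":
        return E[hi] + R[ri] - E[ti]
    if model == "transh":
        w = emb.relation_normals[ri]
        wh = (E[hi] * w).sum(-1, keepdims=True)
        wt = (E[ti] * w).sum(-1, keepdims=True)
        return (E[hi] - wh * w) + R[ri] - (E[ti] - wt * w)
    if model == "transd":
        k = R.shape[1]
        wr = emb.relation_normals[ri]
        ph = (emb.entity_projections[hi] * E[hi]).sum(-1, keepdims=True)
        pt = (emb.entity_projections[ti] * E[ti]).sum(-1, keepdims=True)
        return _rect_identity_apply(E[hi] - E[ti], k) + R[ri] + wr * (ph - pt)
    raise ValueError(model)


def score_triples(emb: EmbeddingSet, triples: Sequence[Triple]) -> np.ndarray:
    """Vectorized scores for a sequence of (head, relation, tail) ids."""
    if len(triples) == 0:
        return np.zeros(0)
    try:
        hi = np.array([emb.entity_index[h] for h, _, _ in triples])
        ti = np.array([emb.entity_index[t] for _, _, t in triples])
    except KeyError as exc:
        raise UnknownEntityError(exc.args[0]) from None
    ri = np.array([emb.relation_index[r] for _, r, _ in triples])
    model = emb.model
    if model == "transe":
        e = _translation_error(emb, hi, ri, ti)
        p = emb.meta.get("norm_order", 2)
        return -np.linalg.norm(e, ord=p, axis=-1) if p == 1 else -np.linalg.norm(e, axis=-1)
    if model in ("transh", "transd"):
        e = _translation_error(emb, hi, ri, ti)
        return -(e ** 2).sum(-1)
    # convkb: z[b, i, j] = F[i] . (h_j, r_j, t_j) + b
    E, R, F = emb.entity_vectors, emb.relation_vectors, emb.conv_filters
    z = (
        F[None, :, 0, None] * E[hi][:, None, :]
        + F[None, :, 1, None] * R[ri][:, None, :]
        + F[None, :, 2, None] * E[ti][:, None, :]
        + emb.conv_bias
    )
    v = np.maximum(z, 0.0)
    tau, d = F.shape[0], E.shape[1]
    w2 = emb.conv_weight.reshape(tau, d)
    return (v * w2[None]).sum(axis=(1, 2))


def score_triple(emb: EmbeddingSet, triple: Triple) -> float:
    """Score a single triple under the embedding set's model."""
    return float(score_triples(emb, [triple])[0])


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    graph_or_entities,
    batch: Sequence[Triple],
    n_neg: int,
    seed: int | np.random.Generator = 0,
) -> list[Triple]:
    """Uniform corruption: each positive yields ``n_neg`` triples with the
    head or the tail (probability 1/2 each) replaced by a uniformly drawn
    entity.  Unfiltered: a corruption may coincide with a true edge."""
    if isinstance(graph_or_entities, LabeledGraph):
        entities = sorted(graph_or_entities.nodes)
    else:
        entities = sorted(graph_or_entities)
    if len(entities) < 2:
        raise ValueError("need at least 2 entities to sample corruptions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_neg == 0 or not batch:
        return []
    m = len(batch) * n_neg
    corrupt_head = rng.random(m) < 0.5
    repl = rng.integers(0, len(entities), size=m)
    out: list[Triple] = []
    for i in range(m):
        h, r, t = batch[i // n_neg]
        e = entities[repl[i]]
        out.append((e, r, t) if corrupt_head[i] else (h, r, e))
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training configuration; mirrors the estimator's parameters so it
    can be round-tripped through YAML/JSON config files."""

    model: str = "transe"
    dim: int = 64
    k_dim: int | None = None
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 0.01
    margin: float = 1.0
    n_negatives: int = 2
    norm_order: int = 2
    n_filters: int = 8
    l2_reg: float = 1e-3
    optimizer: str = "adam"
    normalize_entities: bool = True
    allow_random_convkb_init: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("dim", "epochs", "batch_size", "n_negatives", "n_filters"):
            if getattr(self, name) < 0 or (name in ("dim", "epochs", "batch_size") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class _SGD:
    def __init__(self, params, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


class KnowledgeGraphEmbedding(BaseEstimator):
    """Scikit-learn-style estimator training one of the four KGE models
    on a :class:`~indurank.graph.LabeledGraph`.

    Parameters mirror :class:`TrainConfig`; ``init_from`` may be a fitted
    :class:`KnowledgeGraphEmbedding` or an :class:`EmbeddingSet` and is
    required for ``convkb``/``convkb_d`` (warm start from TransE resp.
    TransD) unless ``allow_random_convkb_init`` is set.

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : EmbeddingSet
    loss_history_ : list[float]      mean loss per epoch
    """

    def __init__(
        self,
        model: str = "transe",
        dim: int = 64,
        k_dim: int | None = None,
        epochs: int = 200,
        batch_size: int = 256,
        learning_rate: float = 0.01,
        margin: float = 1.0,
        n_negatives: int = 2,
        norm_order: int = 2,
        n_filters: int = 8,
        l2_reg: float = 1e-3,
        optimizer: str = "adam",
        normalize_entities: bool = True,
        init_from=None,
        allow_random_convkb_init: bool = False,
        random_state: int = 0,
    ):
        self.model = model
        self.dim = dim
        self.k_dim = k_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.margin = margin
        self.n_negatives = n_negatives
        self.norm_order = norm_order
        self.n_filters = n_filters
        self.l2_reg = l2_reg
        self.optimizer = optimizer
        self.normalize_entities = normalize_entities
        self.init_from = init_from
        self.allow_random_convkb_init = allow_random_convkb_init
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X: LabeledGraph | Iterable[Triple], y=None) -> "KnowledgeGraphEmbedding":
        TrainConfig(  # reuse the dataclass validation
            model=self.model, dim=self.dim, k_dim=self.k_dim, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            margin=self.margin, n_negatives=self.n_negatives, norm_order=self.norm_order,
            n_filters=self.n_filters, l2_reg=self.l2_reg, optimizer=self.optimizer,
            normalize_entities=self.normalize_entities, seed=self.random_state,
        )
        if isinstance(X, LabeledGraph):
            graph = X
        else:
            triples = list(X)
            nodes = {h for h, _, _ in triples} | {t for _, _, t in triples}
            graph = LabeledGraph(frozenset(nodes), frozenset(triples))
        if not graph.edges:
            raise ValueError("graph has no edges")

        entities = sorted(graph.nodes)
        relations = sorted(graph.relations)
        ent_idx = {e: i for i, e in enumerate(entities)}
        rel_idx = {r: i for i, r in enumerate(relations)}
        edges = np.array(
            [(ent_idx[h], rel_idx[r], ent_idx[t]) for h, r, t in graph.sorted_edges()],
            dtype=np.int64,
        )
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(len(entities), len(relations), ent_idx, rel_idx, rng)
        opt_cls = _Adam if self.optimizer == "adam" else _SGD
        opt = opt_cls(params, self.learning_rate)

        n_edges = len(edges)
        bs = min(self.batch_size, n_edges)
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            perm = rng.permutation(n_edges)
            losses = []
            for start in range(0, n_edges, bs):
                batch = edges[perm[start:start + bs]]
                loss = self._step(params, opt, batch, len(entities), rng)
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {_epoch}; reduce the learning rate"
                    )
                losses.append(loss)
            self._apply_constraints(params)
            self.loss_history_.append(float(np.mean(losses)))

        self.entity_index_ = ent_idx
        self.relation_index_ = rel_idx
        self.embedding_ = self._to_embedding_set(params, ent_idx, rel_idx)
        return self

    # -- parameter setup ----------------------------------------------------

    def _init_params(self, n_e, n_r, ent_idx, rel_idx, rng) -> dict[str, np.ndarray]:
        d = self.dim
        k = self.k_dim or d
        lim = math.sqrt(6.0 / d)
        params: dict[str, np.ndarray] = {}
        if self.model in ("convkb", "convkb_d"):
            init = self.init_from
            if init is None:
                if not self.allow_random_convkb_init:
                    raise ValueError(
                        f"{self.model} should be initialized from pretrained "
                        "translational embeddings (init_from); pass "
                        "allow_random_convkb_init=True to override"
                    )
                params["E"] = rng.uniform(-lim, lim, (n_e, d))
                params["R"] = rng.uniform(-lim, lim, (n_r, d))
            else:
                emb = init.embedding_ if isinstance(init, KnowledgeGraphEmbedding) else init
                expected = "transd" if self.model == "convkb_d" else "transe"
                if emb.model != expected:
                    raise ValueError(f"{self.model} must be initialized from {expected} embeddings")
                if emb.dim != d or emb.relation_vectors.shape[1] != d:
                    raise ValueError(
                        f"init_from dimension {emb.dim} does not match dim={d}"
                    )
                try:
                    params["E"] = np.stack([emb.entity_vectors[emb.entity_index[e]] for e in ent_idx])
                    params["R"] = np.stack([emb.relation_vectors[emb.relation_index[r]] for r in rel_idx])
                except KeyError as exc:
                    raise ValueError(f"init_from lacks vocabulary entry {exc.args[0]!r}") from None
            tau = self.n_filters
            params["F"] = np.tile([[0.1, 0.1, -0.1]], (tau, 1)) + rng.normal(0, 0.01, (tau, 3))
            params["w"] = rng.uniform(-math.sqrt(6.0 / (tau * d)), math.sqrt(6.0 / (tau * d)), tau * d)
            params["b"] = np.zeros(1)
            return params

        params["E"] = rng.uniform(-lim, lim, (n_e, d))
        if self.model == "transe":
            params["R"] = rng.uniform(-lim, lim, (n_r, d))
        elif self.model == "transh":
            params["R"] = rng.uniform(-lim, lim, (n_r, d))
            w = rng.uniform(-lim, lim, (n_r, d))
            params["Wr"] = w / np.linalg.norm(w, axis=1, keepdims=True)
        elif self.model == "transd":
            limk = math.sqrt(6.0 / k)
            params["R"] = rng.uniform(-limk, limk, (n_r, k))
            params["Wr"] = rng.uniform(-limk, limk, (n_r, k))
            params["P"] = np.zeros((n_e, d))
        return params

    def _apply_constraints(self, params):
        if self.model in ("transe", "transh", "transd") and self.normalize_entities:
            norms = np.linalg.norm(params["E"], axis=1, keepdims=True)
            np.divide(params["E"], norms, out=params["E"], where=norms > 1.0)
        if self.model == "transh":
            params["Wr"] /= np.linalg.norm(params["Wr"], axis=1, keepdims=True)

    # -- one optimization step ---------------------------------------------

    def _step(self, params, opt, batch, n_e, rng) -> float:
        n_neg = max(self.n_negatives, 1)
        pos = np.repeat(batch, n_neg, axis=0)
        neg = pos.copy()
        m = len(neg)
        corrupt_head = rng.random(m) < 0.5
        repl = rng.integers(0, n_e, size=m)
        neg[corrupt_head, 0] = repl[corrupt_head]
        neg[~corrupt_head, 2] = repl[~corrupt_head]

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        if self.model in ("convkb", "convkb_d"):
            s_pos, cache_p = self._convkb_forward(params, pos)
            s_neg, cache_n = self._convkb_forward(params, neg)
            # soft-margin logistic loss over labeled samples
            y = np.concatenate([np.ones(m), -np.ones(m)])
            s = np.concatenate([s_pos, s_neg])
            z = -y * s
            loss = float(np.mean(np.logaddexp(0.0, z)))
            coeff = (-y * _sigmoid(z)) / (2 * m)
            self._convkb_backward(params, grads, pos, cache_p, coeff[:m])
            self._convkb_backward(params, grads, neg, cache_n, coeff[m:])
            loss += 0.5 * self.l2_reg * float(params["w"] @ params["w"])
            grads["w"] += self.l2_reg * params["w"]
        else:
            s_pos = self._trans_score(params, pos)
            s_neg = self._trans_score(params, neg)
            viol = self.margin - s_pos + s_neg
            active = viol > 0
            loss = float(np.mean(np.maximum(viol, 0.0)))
            coeff_pos = np.where(active, -1.0, 0.0) / m
            coeff_neg = np.where(active, 1.0, 0.0) / m
            self._trans_backward(params, grads, pos, coeff_pos)
            self._trans_backward(params, grads, neg, coeff_neg)
        opt.step(params, grads)
        self._apply_constraints(params)
        return loss

    # -- translational forward/backward --------------------------------------

    def _trans_error(self, params, batch):
        E, R = params["E"], params["R"]
        hi, ri, ti = batch[:, 0], batch[:, 1], batch[:, 2]
        if self.model == "transe":
            return E[hi] + R[ri] - E[ti]
        if self.model == "transh":
            w = params["Wr"][ri]
            u = E[ti] - E[hi]
            c = (w * u).sum(-1, keepdims=True)
            return E[hi] - E[ti] + R[ri] + c * w
        # transd
        k = R.shape[1]
        wr = params["Wr"][ri]
        ph = (params["P"][hi] * E[hi]).sum(-1, keepdims=True)
        pt = (params["P"][ti] * E[ti]).sum(-1, keepdims=True)
        return _rect_identity_apply(E[hi] - E[ti], k) + R[ri] + wr * (ph - pt)

    def _trans_score(self, params, batch):
        e = self._trans_error(params, batch)
        if self.model == "transe":
            if self.norm_order == 1:
                return -np.abs(e).sum(-1)
            return -np.sqrt((e ** 2).sum(-1) + 1e-12)
        return -(e ** 2).sum(-1)

    def _trans_backward(self, params, grads, batch, coeff):
        """Accumulate coeff[i] * d score_i / d theta into grads."""
        E, R = params["E"], params["R"]
        hi, ri, ti = batch[:, 0], batch[:, 1], batch[:, 2]
        e = self._trans_error(params, batch)
        if self.model == "transe":
            if self.norm_order == 1:
                de = np.sign(e)
            else:
                de = e / np.sqrt((e ** 2).sum(-1, keepdims=True) + 1e-12)
            g = -coeff[:, None] * de          # d score = -d dist
            np.add.at(grads["E"], hi, g)
            np.add.at(grads["R"], ri, g)
            np.add.at(grads["E"], ti, -g)
            return
        de = 2.0 * e                          # d dist / d e ; score = -dist
        if self.model == "transh":
            w = params["Wr"][ri]
            u = E[ti] - E[hi]
            we = (w * de).sum(-1, keepdims=True)
            c = (w * u).sum(-1, keepdims=True)
            g_h = -coeff[:, None] * (de - we * w)      # P_w is symmetric
            np.add.at(grads["E"], hi, g_h)
            np.add.at(grads["E"], ti, -g_h)
            np.add.at(grads["R"], ri, -coeff[:, None] * de)
            g_w = -coeff[:, None] * (we * u + c * de)
            np.add.at(grads["Wr"], ri, g_w)
            return
        # transd
        d = E.shape[1]
        wr = params["Wr"][ri]
        wre = (wr * de).sum(-1, keepdims=True)        # w_r . (d dist/d e)
        deT = _rect_identity_applyT(de, d)
        ph = (params["P"][hi] * E[hi]).sum(-1, keepdims=True)
        pt = (params["P"][ti] * E[ti]).sum(-1, keepdims=True)
        np.add.at(grads["E"], hi, -coeff[:, None] * (deT + wre * params["P"][hi]))
        np.add.at(grads["E"], ti, coeff[:, None] * (deT + wre * params["P"][ti]))
        np.add.at(grads["P"], hi, -coeff[:, None] * (wre * E[hi]))
        np.add.at(grads["P"], ti, coeff[:, None] * (wre * E[ti]))
        np.add.at(grads["R"], ri, -coeff[:, None] * de)
        np.add.at(grads["Wr"], ri, -coeff[:, None] * ((ph - pt) * de))

    # -- convkb forward/backward ---------------------------------------------

    def _convkb_forward(self, params, batch):
        E, R, F = params["E"], params["R"], params["F"]
        hi, ri, ti = batch[:, 0], batch[:, 1], batch[:, 2]
        z = (
            F[None, :, 0, None] * E[hi][:, None, :]
            + F[None, :, 1, None] * R[ri][:, None, :]
            + F[None, :, 2, None] * E[ti][:, None, :]
            + params["b"][0]
        )
        v = np.maximum(z, 0.0)
        tau, d = F.shape[0], E.shape[1]
        w2 = params["w"].reshape(tau, d)
        s = (v * w2[None]).sum(axis=(1, 2))
        return s, (z, v)

    def _convkb_backward(self, params, grads, batch, cache, coeff):
        E, R, F = params["E"], params["R"], params["F"]
        hi, ri, ti = batch[:, 0], batch[:, 1], batch[:, 2]
        z, v = cache
        tau, d = F.shape[0], E.shape[1]
        w2 = params["w"].reshape(tau, d)
        mask = (z > 0).astype(float)
        grads["w"] += (coeff[:, None, None] * v).sum(0).reshape(-1)
        wm = w2[None] * mask                         # (B, tau, d)
        cw = coeff[:, None, None] * wm
        np.add.at(grads["E"], hi, (cw * F[None, :, 0, None]).sum(1))
        np.add.at(grads["R"], ri, (cw * F[None, :, 1, None]).sum(1))
        np.add.at(grads["E"], ti, (cw * F[None, :, 2, None]).sum(1))
        grads["F"][:, 0] += (cw * E[hi][:, None, :]).sum(axis=(0, 2))
        grads["F"][:, 1] += (cw * R[ri][:, None, :]).sum(axis=(0, 2))
        grads["F"][:, 2] += (cw * E[ti][:, None, :]).sum(axis=(0, 2))
        grads["b"][0] += cw.sum()

    # -- export ---------------------------------------------------------------

    def _to_embedding_set(self, params, ent_idx, rel_idx) -> EmbeddingSet:
        meta = {
            "model": self.model, "dim": self.dim, "k_dim": self.k_dim or self.dim,
            "epochs": self.epochs, "seed": self.random_state,
            "norm_order": self.norm_order, "n_filters": self.n_filters,
        }
        return EmbeddingSet(
            model=self.model,
            entity_index=dict(ent_idx),
            relation_index=dict(rel_idx),
            entity_vectors=params["E"].copy(),
            relation_vectors=params["R"].copy(),
            relation_normals=params.get("Wr", None).copy() if "Wr" in params else None,
            entity_projections=params.get("P", None).copy() if "P" in params else None,
            conv_filters=params["F"].copy() if "F" in params else None,
            conv_weight=params["w"].copy() if "w" in params else None,
            conv_bias=float(params["b"][0]) if "b" in params else None,
            meta=meta,
        )

    def score_triples(self, triples: Sequence[Triple]) -> np.ndarray:
        if not hasattr(self, "embedding_"):
            raise RuntimeError("estimator is not fitted")
        return score_triples(self.embedding_, triples)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def train(graph: LabeledGraph, config: TrainConfig, init_from=None) -> EmbeddingSet:
    """Functional wrapper: train embeddings on a graph per ``config``."""
    est = KnowledgeGraphEmbedding(
        model=config.model, dim=config.dim, k_dim=config.k_dim, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        margin=config.margin, n_negatives=config.n_negatives,
        norm_order=config.norm_order, n_filters=config.n_filters, l2_reg=config.l2_reg,
        optimizer=config.optimizer, normalize_entities=config.normalize_entities,
        init_from=init_from, allow_random_convkb_init=config.allow_random_convkb_init,
        random_state=config.seed,
    )
    est.fit(graph)
    return est.embedding_
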