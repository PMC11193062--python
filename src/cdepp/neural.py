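"""Metric-learning sequence embedders, the subtree classifier, and model selection.

An embedder maps an aligned sequence to a point in R^d so that Euclidean
distances between embeddings match patristic distances on the backbone; the
training objective is

    sum_{i<j} (1/d_ij) * (||Phi(s_i) - Phi(s_j)||_2 - d_ij)^2 ,

minimized by Adam over mini-batches (within-batch pairs only).  The
classifier shares the same trunk but ends in a softmax over all second-level
clusters; a query's first-level score is the maximum probability among the
second-level clusters inside that first-level cluster, and up to
``max_models`` first-level clusters are selected as long as each score is at
least ``ratio`` times the previously selected one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import (
    Adam,
    TrunkNet,
    pairwise_distance_loss,
    softmax,
    softmax_cross_entropy,
)
from .encoding import EncodedAlignment, one_hot_encode
from .trees import DistanceMatrix

__all__ = [
    "SequenceEmbedder",
    "SubtreeClassifier",
    "ModelSelection",
    "depp_loss",
    "train_embedder",
    "embed_distances",
    "train_classifier",
    "first_level_scores",
    "select_models",
]

DEFAULT_MAX_MODELS = 4
DEFAULT_RATIO = 1.0 / 200.0


def depp_loss(points, dmat, return_excluded: bool = False):
    """Metric-matching loss over unordered pairs; zero-distance pairs excluded.

    ``points`` is an (n, d) array; ``dmat`` a matching (n, n) array or
    :class:`DistanceMatrix`.  With ``return_excluded`` also returns the count
    of excluded zero-distance pairs (a diagnostics field).
    """
    D = dmat.values if isinstance(dmat, DistanceMatrix) else np.asarray(dmat, float)
    P = np.asarray(points, float)
    if P.ndim != 2 or D.shape != (P.shape[0], P.shape[0]):
        raise ValueError(
            f"dimension mismatch: {P.shape} points vs {D.shape} distance matrix"
        )
    loss, n_excluded = pairwise_distance_loss(P, D)
    if return_excluded:
        return loss, n_excluded
    return loss


def _as_encoded(X) -> EncodedAlignment:
    if isinstance(X, EncodedAlignment):
        return X
    return one_hot_encode(X)


class SequenceEmbedder(TransformerMixin, BaseEstimator):
    """Per-cluster sequence embedder trained to match patristic distances.

    Parameters
    ----------
    embedding_dim : output dimensionality d (128 at reference scale, 16 in
        the scaled-down test profile).
    channels : channel count of the convolutional trunk.
    epochs, lr, batch_size : Adam training schedule; each mini-batch uses
        only its within-batch pairs.
    seed : seed for initialization and batch shuffling; training is
        deterministic given the seed.

    Fitted attributes
    -----------------
    net_ : trained trunk network.
    labels_ : training taxa order.
    initial_loss_, final_loss_ : full-training-set loss before/after
        training (``final_loss_ <= initial_loss_``).
    n_excluded_pairs_ : zero-distance training pairs dropped from the loss.
    """

    def __init__(self, embedding_dim: int = 16, channels: int = 32,
                 epochs: int = 200, lr: float = 1e-3, batch_size: int = 32,
                 seed: int = 0, eval_every: int = 10, cluster_id: int | None = None):
        self.embedding_dim = embedding_dim
        self.channels = channels
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.eval_every = eval_every
        self.cluster_id = cluster_id

    def fit(self, X, y=None):
        enc = _as_encoded(X)
        if isinstance(y, DistanceMatrix):
            D = y.submatrix(enc.labels).values
        else:
            D = np.asarray(y, float)
        n = len(enc.labels)
        if n < 2:
            raise ValueError(
                "cannot train an embedder on a single sequence; merge this "
                "cluster with a neighbor"
            )
        if D.shape != (n, n):
            raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
        off = ~np.eye(n, dtype=bool)
        if not np.any(D[off] > 0):
            raise ValueError(
                "all pairwise distances are zero (identical sequences?); "
                "nothing to train on"
            )
        rng = np.random.default_rng(self.seed)
        net = TrunkNet(enc.length, self.embedding_dim, self.channels,
                       seed=int(rng.integers(0, 2**31 - 1)))
        opt = Adam(net, lr=self.lr)
        Xall = enc.data

        def full_loss():
            E = net.forward(Xall)
            l, nex = pairwise_distance_loss(E, D)
            return l, nex

        self.initial_loss_, self.n_excluded_pairs_ = full_loss()
        best_loss, best_params = self.initial_loss_, net.copy_params()
        bs = max(2, int(self.batch_size))
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            for s in range(0, n, bs):
                idx = perm[s:s + bs]
                if idx.size < 2:
                    continue
                E, cache = net.forward(Xall[idx], cache=True)
                _, _, dE = pairwise_distance_loss(E, D[np.ix_(idx, idx)],
                                                  return_grad=True)
                opt.step(net.backward(dE, cache))
            if (epoch + 1) % self.eval_every == 0 or epoch == self.epochs - 1:
                l, _ = full_loss()
                if l < best_loss:
                    best_loss, best_params = l, net.copy_params()
        net.set_params_(best_params)
        self.net_ = net
        self.labels_ = enc.labels
        self.seq_len_ = enc.length
        self.final_loss_ = best_loss
        self.training_embeddings_ = net.forward(Xall)
        return self

    def transform(self, X) -> np.ndarray:
        enc = _as_encoded(X)
        self._check_len(enc.length)
        return self.net_.forward(enc.data)

    def embed_one(self, row: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        self._check_len(row.shape[0])
        return self.net_.forward(row[None])[0]

    def _check_len(self, L: int):
        if not hasattr(self, "net_"):
            raise ValueError("embedder is not fitted")
        if L != self.seq_len_:
            raise ValueError(
                f"sequence length {L} does not match trained length {self.seq_len_}"
            )

    # -- persistence ----------------------------------------------------
    def get_state(self) -> dict:
        return {
            "config": self.get_params(),
            "net": self.net_.get_state(),
            "labels": list(self.labels_),
            "initial_loss": self.initial_loss_,
            "final_loss": self.final_loss_,
            "n_excluded_pairs": self.n_excluded_pairs_,
            "embeddings": np.asarray(self.training_embeddings_).tolist(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "SequenceEmbedder":
        est = cls(**state["config"])
        est.net_ = TrunkNet.from_state(state["net"])
        est.labels_ = tuple(state["labels"])
        est.seq_len_ = est.net_.seq_len
        est.initial_loss_ = state["initial_loss"]
        est.final_loss_ = state["final_loss"]
        est.n_excluded_pairs_ = state["n_excluded_pairs"]
        est.training_embeddings_ = np.asarray(state["embeddings"], dtype=np.float64)
        return est


class SubtreeClassifier(BaseEstimator):
    """Softmax classifier over second-level clusters, same trunk as the embedder.

    ``fit(X, y)`` takes integer class labels (one per taxon); every class in
    ``0..K-1`` must have at least one member.  ``predict_proba`` returns a
    probability vector per input (non-negative, summing to 1).
    ``label_map`` optionally records, per class index, the
    (first_level, second_level) pair it stands for.
    """

    def __init__(self, channels: int = 32, epochs: int = 300, lr: float = 1e-3,
                 batch_size: int = 32, seed: int = 0, eval_every: int = 20,
                 label_map: list | None = None):
        self.channels = channels
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.eval_every = eval_every
        self.label_map = label_map

    def fit(self, X, y):
        enc = _as_encoded(X)
        y = np.asarray(y, dtype=int)
        if y.shape != (len(enc.labels),):
            raise ValueError("one label per taxon required")
        K = int(y.max()) + 1
        counts = np.bincount(y, minlength=K)
        if np.any(counts == 0):
            empty = np.nonzero(counts == 0)[0].tolist()
            raise ValueError(f"classes with zero members: {empty}")
        rng = np.random.default_rng(self.seed)
        net = TrunkNet(enc.length, K, self.channels,
                       seed=int(rng.integers(0, 2**31 - 1)))
        opt = Adam(net, lr=self.lr)
        Xall, n = enc.data, len(enc.labels)

        def full_loss():
            return softmax_cross_entropy(net.forward(Xall), y)

        self.initial_loss_ = full_loss()
        best_loss, best_params = self.initial_loss_, net.copy_params()
        bs = max(2, int(self.batch_size))
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            for s in range(0, n, bs):
                idx = perm[s:s + bs]
                out, cache = net.forward(Xall[idx], cache=True)
                _, dZ = softmax_cross_entropy(out, y[idx], return_grad=True)
                opt.step(net.backward(dZ, cache))
            if (epoch + 1) % self.eval_every == 0 or epoch == self.epochs - 1:
                l = full_loss()
                if l < best_loss:
                    best_loss, best_params = l, net.copy_params()
        net.set_params_(best_params)
        self.net_ = net
        self.labels_ = enc.labels
        self.seq_len_ = enc.length
        self.n_classes_ = K
        self.final_loss_ = best_loss
        return self

    def predict_proba(self, X) -> np.ndarray:
        enc = _as_encoded(X)
        if enc.length != self.seq_len_:
            raise ValueError(
                f"sequence length {enc.length} does not match trained length "
                f"{self.seq_len_}"
            )
        return softmax(self.net_.forward(enc.data))

    def predict_proba_one(self, row: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        if row.shape[0] != self.seq_len_:
            raise ValueError("sequence length mismatch")
        return softmax(self.net_.forward(row[None]))[0]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def get_state(self) -> dict:
        return {
            "config": self.get_params(),
            "net": self.net_.get_state(),
            "labels": list(self.labels_),
            "initial_loss": self.initial_loss_,
            "final_loss": self.final_loss_,
        }

    @classmethod
    def from_state(cls, state: dict) -> "SubtreeClassifier":
        est = cls(**state["config"])
        est.net_ = TrunkNet.from_state(state["net"])
        est.labels_ = tuple(state["labels"])
        est.seq_len_ = est.net_.seq_len
        est.n_classes_ = est.net_.out_dim
        est.initial_loss_ = state["initial_loss"]
        est.final_loss_ = state["final_loss"]
        return est


# ---------------------------------------------------------------------------
# Functional wrappers and the selection rule
# ---------------------------------------------------------------------------

def train_embedder(encoded, dmat, **config) -> SequenceEmbedder:
    """Train a :class:`SequenceEmbedder`; see the class for the contract."""
    return SequenceEmbedder(**config).fit(encoded, dmat)


def train_classifier(encoded, labels, **config) -> SubtreeClassifier:
    """Train a :class:`SubtreeClassifier` on integer second-level labels."""
    return SubtreeClassifier(**config).fit(encoded, labels)


def embed_distances(model: SequenceEmbedder, query_row: np.ndarray,
                    backbone: EncodedAlignment) -> dict[str, float]:
    """Euclidean distances from a query's embedding to backbone embeddings.

    Only the supplied backbone subset (typically the model's augmented
    cluster) is covered; values are non-negative by construction.
    """
    q = model.embed_one(query_row)
    E = model.transform(backbone)
    d = np.sqrt(((E - q[None]) ** 2).sum(axis=1))
    return {lab: float(v) for lab, v in zip(backbone.labels, d)}


@dataclass
class ModelSelection:
    """Ordered first-level clusters chosen for a query, with their scores."""

    selected: list[tuple[int, float]]
    max_models: int = DEFAULT_MAX_MODELS
    ratio: float = DEFAULT_RATIO

    def __post_init__(self):
        if not 1 <= len(self.selected) <= self.max_models:
            raise ValueError("selection size out of bounds")
        scores = [s for _, s in self.selected]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("selection scores must be non-increasing")

    @property
    def cluster_ids(self) -> list[int]:
        return [cid for cid, _ in self.selected]


def first_level_scores(probs: np.ndarray, label_map) -> dict[int, float]:
    """Pool second-level probabilities to first-level scores by max.

    ``label_map[j]`` gives the (first_level, second_level) pair of output
    index j; the score of first-level cluster i is the maximum probability
    among its second-level clusters.
    """
    probs = np.asarray(probs, float)
    scores: dict[int, float] = {}
    for p, (i, _) in zip(probs, label_map):
        if i not in scores or p > scores[i]:
            scores[i] = float(p)
    return scores


def select_models(scores: dict[int, float], max_models: int = DEFAULT_MAX_MODELS,
                  ratio: float = DEFAULT_RATIO) -> ModelSelection:
    """Greedy top-score selection with a relative-likelihood cutoff.

    Sort scores descending (ties by cluster id); always take the top; keep
    taking while fewer than ``max_models`` are selected and the next score is
    at least ``ratio`` times the previously taken score.
    """
    if not scores:
        raise ValueError("no scores to select from")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    taken = [ranked[0]]
    for cid, s in ranked[1:]:
        if len(taken) >= max_models:
            break
        if s < taken[-1][1] * ratio:
            break
        taken.append((cid, s))
    return ModelSelection([(c, float(s)) for c, s in taken],
                          max_models=max_models, ratio=ratio)
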