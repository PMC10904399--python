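"""Siamese pair classifier for compound / genetic-perturbation signatures.

Both signature vectors pass through one shared dense layer D(x); the outputs
are element-wise multiplied — a symmetric merge, so the score is invariant to
swapping the two inputs — and a two-layer head with a sigmoid output yields
the probability that the pair shares a target.  Training is balanced per
target gene (one sampled negative compound per positive pair), uses binary
cross-entropy, and predictions average a small ensemble of independently
initialized models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .signature import SignatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "PairExample",
    "SiameseParams",
    "siamese_forward",
    "bce_loss",
    "balanced_pair_sampling",
    "compound_kfold",
    "CoTargetClassifier",
    "train_cotarget_model",
]

_PROB_CLIP = 1e-7


@dataclass
class PairExample:
    """A (compound signature, genetic signature) pair with its co-target label."""

    compound_vec: np.ndarray
    gene_vec: np.ndarray
    label: int
    compound_id: str = ""
    target_gene: str = ""
    cell_line: str = ""
    perturbagen_type: str = "shRNA"

    def __post_init__(self):
        self.compound_vec = np.asarray(self.compound_vec, dtype=float)
        self.gene_vec = np.asarray(self.gene_vec, dtype=float)
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.compound_vec.shape != self.gene_vec.shape:
            raise ValueError("pair vectors must share a dimension")

    @classmethod
    def from_signatures(cls, compound: SignatureVector, gene: SignatureVector,
                        label: int, target_gene: str = "") -> "PairExample":
        return cls(compound.vector, gene.vector, label,
                   compound.perturbagen_id, target_gene, compound.cell_line,
                   gene.perturbagen_type)


@dataclass
class SiameseParams:
    """Weights of the shared layer and the classification head."""

    W1: np.ndarray  # dim x h1 (shared)
    b1: np.ndarray
    W2: np.ndarray  # h1 x h2
    b2: np.ndarray
    W3: np.ndarray  # h2 x 1
    b3: np.ndarray
    seed: int = 0

    @classmethod
    def init(cls, dim: int, hidden1: int = 2048, hidden2: int = 512,
             seed: int = 0) -> "SiameseParams":
        rng = np.random.default_rng(seed)
        def he(n_in, n_out):
            return rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out))
        return cls(he(dim, hidden1), np.zeros(hidden1),
                   he(hidden1, hidden2), np.zeros(hidden2),
                   he(hidden2, 1), np.zeros(1), seed)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _forward(params: SiameseParams, A: np.ndarray, B: np.ndarray):
    z1a = A @ params.W1 + params.b1
    z1b = B @ params.W1 + params.b1
    h1a, h1b = _relu(z1a), _relu(z1b)
    m = h1a * h1b
    z2 = m @ params.W2 + params.b2
    h2 = _relu(z2)
    o = _sigmoid(h2 @ params.W3 + params.b3).ravel()
    return o, (z1a, z1b, h1a, h1b, m, z2, h2)


def siamese_forward(params: SiameseParams, pair: PairExample) -> float:
    """Co-targeting probability for one pair."""
    if pair.compound_vec.shape[0] != params.W1.shape[0]:
        raise ValueError(
            f"input dim {pair.compound_vec.shape[0]} does not match "
            f"model dim {params.W1.shape[0]}")
    o, _ = _forward(params, pair.compound_vec[None, :], pair.gene_vec[None, :])
    return float(o[0])


def bce_loss(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Summed binary cross-entropy; probabilities clipped away from {0, 1}."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        logger.info("probabilities clipped to (%g, %g) before the log",
                    _PROB_CLIP, 1 - _PROB_CLIP)
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def balanced_pair_sampling(positives: Sequence[PairExample],
                           compound_vectors: dict[str, np.ndarray],
                           seed: int = 0,
                           annotations: dict[str, set[str]] | None = None
                           ) -> list[PairExample]:
    """Add one sampled negative per positive, balanced per target gene.

    For every positive pair (c, g) a compound NOT annotated to target g is
    drawn (uniformly, with replacement across pairs) from
    ``compound_vectors`` and paired with the same genetic signature, labeled
    0.  Annotations default to the compound->target map implied by the
    positive pairs themselves.  Returns positives plus sampled negatives.
    """
    rng = np.random.default_rng(seed)
    if annotations is None:
        annotations = {}
        for p in positives:
            annotations.setdefault(p.compound_id, set()).add(p.target_gene)
    all_compounds = sorted(compound_vectors)
    out = list(positives)
    for p in positives:
        eligible = [c for c in all_compounds
                    if p.target_gene not in annotations.get(c, set())]
        if not eligible:
            raise ValueError(
                f"no compound available as a negative for gene {p.target_gene!r}")
        c = eligible[rng.integers(len(eligible))]
        out.append(PairExample(compound_vectors[c], p.gene_vec, 0, c,
                               p.target_gene, p.cell_line, p.perturbagen_type))
    return out


def compound_kfold(compound_ids: Sequence[str], n_splits: int = 5,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold over examples, split by compound identity so no compound
    appears in both the training and validation side of a fold."""
    ids = np.asarray(compound_ids, dtype=object)
    uniq = np.array(sorted(set(compound_ids)), dtype=object)
    if len(uniq) < n_splits:
        raise ValueError(f"need at least {n_splits} distinct compounds")
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    chunks = np.array_split(uniq, n_splits)
    folds = []
    for chunk in chunks:
        val = np.isin(ids, chunk)
        folds.append((np.flatnonzero(~val), np.flatnonzero(val)))
    return folds


class CoTargetClassifier:
    """Ensemble of Siamese networks scoring compound/gene signature pairs.

    sklearn-style estimator: ``fit(X, y)`` with X of shape (n, 2, dim) —
    X[:, 0] the compound signature vectors, X[:, 1] the genetic ones — and
    binary y.  ``predict_proba`` follows the sklearn two-column convention;
    ``decision_scores`` returns the raw ensemble-mean co-targeting
    probability.

    Defaults follow the reference architecture: a 2048-unit shared layer, a
    512-unit hidden layer, sigmoid output, 60 training epochs, and a 3-model
    ensemble whose predictions are averaged.
    """

    def __init__(self, hidden1: int = 2048, hidden2: int = 512,
                 epochs: int = 60, n_models: int = 3, batch_size: int = 128,
                 learning_rate: float = 1e-3, random_state: int = 0):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.epochs = epochs
        self.n_models = n_models
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    _param_names = ("hidden1", "hidden2", "epochs", "n_models", "batch_size",
                    "learning_rate", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "CoTargetClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- training ----------------------------------------------------------
    def _train_one(self, A: np.ndarray, B: np.ndarray, y: np.ndarray,
                   seed: int) -> tuple[SiameseParams, list[float]]:
        params = SiameseParams.init(A.shape[1], self.hidden1, self.hidden2, seed)
        rng = np.random.default_rng(seed + 1)
        n = A.shape[0]
        adam = {k: [np.zeros_like(getattr(params, k)),
                    np.zeros_like(getattr(params, k))]
                for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        t = 0
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                o, cache = _forward(params, A[idx], B[idx])
                z1a, z1b, h1a, h1b, m, z2, h2 = cache
                yb = y[idx]
                epoch_loss += bce_loss(o, yb)
                g3 = ((o - yb) / len(idx))[:, None]       # d(mean BCE)/dz3
                grads = {
                    "W3": h2.T @ g3, "b3": g3.sum(axis=0)}
                dh2 = g3 @ params.W3.T
                dz2 = dh2 * (z2 > 0)
                grads["W2"] = m.T @ dz2
                grads["b2"] = dz2.sum(axis=0)
                dm = dz2 @ params.W2.T
                dz1a = dm * h1b * (z1a > 0)
                dz1b = dm * h1a * (z1b > 0)
                grads["W1"] = A[idx].T @ dz1a + B[idx].T @ dz1b
                grads["b1"] = dz1a.sum(axis=0) + dz1b.sum(axis=0)
                t += 1
                for k, g in grads.items():
                    mom, vel = adam[k]
                    mom[:] = b1m * mom + (1 - b1m) * g
                    vel[:] = b2m * vel + (1 - b2m) * g ** 2
                    step = self.learning_rate * (mom / (1 - b1m ** t)) / \
                        (np.sqrt(vel / (1 - b2m ** t)) + eps)
                    getattr(params, k)[:] = getattr(params, k) - step
            history.append(epoch_loss / n)
        return params, history

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "CoTargetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_pairs, 2, dim)")
        if len(np.unique(y)) < 2:
            raise ValueError("training pairs must contain both labels")
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.n_models)
        self.models_ = []
        self.loss_histories_ = []
        for s in seeds:
            params, hist = self._train_one(X[:, 0], X[:, 1], y, int(s) % (2**31))
            self.models_.append(params)
            self.loss_histories_.append(hist)
        self.n_features_in_ = X.shape[2]
        self.classes_ = np.array([0, 1])
        return self

    # -- inference ---------------------------------------------------------
    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-mean co-targeting probability per pair."""
        if not hasattr(self, "models_"):
            raise RuntimeError("CoTargetClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        probs = [_forward(p, X[:, 0], X[:, 1])[0] for p in self.models_]
        return np.mean(probs, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)

    def score_pairs(self, pairs: Sequence[PairExample]) -> np.ndarray:
        X = np.stack([[p.compound_vec, p.gene_vec] for p in pairs])
        return self.decision_scores(X)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Portable checkpoint: JSON config plus per-model weight arrays in
        a single .npz container."""
        arrays = {}
        for i, p in enumerate(self.models_):
            for k in ("W1", "b1", "W2", "b2", "W3", "b3"):
                arrays[f"model{i}_{k}"] = getattr(p, k)
            arrays[f"model{i}_seed"] = np.array(p.seed)
        arrays["config"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CoTargetClassifier":
        with np.load(path) as data:
            config = json.loads(bytes(data["config"]).decode())
            clf = cls(**config)
            clf.models_ = []
            i = 0
            while f"model{i}_W1" in data:
                clf.models_.append(SiameseParams(
                    *(data[f"model{i}_{k}"] for k in
                      ("W1", "b1", "W2", "b2", "W3", "b3")),
                    seed=int(data[f"model{i}_seed"])))
                i += 1
        clf.n_features_in_ = clf.models_[0].W1.shape[0]
        clf.classes_ = np.array([0, 1])
        return clf


def _count_targets(examples: Iterable[PairExample]) -> dict[str, set[str]]:
    targets: dict[str, set[str]] = {}
    for e in examples:
        if e.label == 1:
            targets.setdefault(e.compound_id, set()).add(e.target_gene)
    return targets


def train_cotarget_model(examples: Sequence[PairExample], epochs: int = 60,
                         n_models: int = 3, seed: int = 0,
                         max_targets: int = 5,
                         **kwargs) -> CoTargetClassifier:
    """Train the ensemble, excluding promiscuous compounds.

    Compounds positively annotated to more than ``max_targets`` target genes
    are dropped from the training pairs (polypharmacology filter); the
    number of dropped pairs is logged.
    """
    targets = _count_targets(examples)
    promiscuous = {c for c, ts in targets.items() if len(ts) > max_targets}
    kept = [e for e in examples if e.compound_id not in promiscuous]
    if len(kept) < len(examples):
        logger.info("excluded %d pairs from %d compounds with more than %d "
                    "annotated targets", len(examples) - len(kept),
                    len(promiscuous), max_targets)
    if not kept:
        raise ValueError("no training pairs left after the target-count filter")
    X = np.stack([[e.compound_vec, e.gene_vec] for e in kept])
    y = np.array([e.label for e in kept])
    clf = CoTargetClassifier(epochs=epochs, n_models=n_models,
                             random_state=seed, **kwargs)
    return clf.fit(X, y)
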