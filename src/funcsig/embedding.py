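"""Contrastive gene embeddings trained on hypergraph random-walk samples.

For each gene u, positives N(u) are drawn proportionally to the stationary
random-walk-with-restart distribution from u and negatives R(u) inversely
proportionally, at a 1:5 ratio.  Embeddings minimize the negative-sampling
objective -Σ_v log σ(x_v·x_u) - Σ_z log σ(-x_z·x_u), so functionally close
genes acquire similar vectors.  Each annotation modality (ontology terms,
expression-derived gene sets) yields a 256-dimensional embedding by default;
the two are concatenated into the joint gene representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .graph import (FunctionalHypergraph, GeneUniverse, StationaryProfile,
                    build_transition_matrix, sample_neighbors, stationary_matrix)

__all__ = [
    "EmbeddingMatrix",
    "ContrastiveBatch",
    "contrastive_loss",
    "GeneEmbedder",
    "train_embeddings",
    "concat_modalities",
    "write_embedding_table",
    "read_embedding_table",
]

_DOT_CLAMP = 30.0  # dot products clipped here before the sigmoid


@dataclass
class EmbeddingMatrix:
    """Per-gene vectors for one modality (or the ordered concatenation)."""

    universe: GeneUniverse
    vectors: np.ndarray  # |V| x dim
    modality: str = "expression"
    isolated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.universe):
            raise ValueError("one vector per gene required")
        if self.modality not in ("ontology", "expression", "concat"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        try:
            return self.vectors[self.universe.index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in embedding universe") from None

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy; zero rows stay zero (cosine treated as 0)."""
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        return np.divide(self.vectors, norms, out=np.zeros_like(self.vectors),
                         where=norms > 0)


@dataclass
class ContrastiveBatch:
    """Anchor gene with sampled positive and negative multisets."""

    anchor: str
    positives: list[str]
    negatives: list[str]

    def __post_init__(self):
        if self.anchor in self.positives or self.anchor in self.negatives:
            raise ValueError("anchor must not appear among its own samples")


def _sigma(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_DOT_CLAMP, _DOT_CLAMP)))


def contrastive_loss(batch: ContrastiveBatch, emb: EmbeddingMatrix) -> float:
    """Negative log-likelihood of one anchor's positive/negative samples."""
    xu = emb.vector(batch.anchor)
    pos = np.array([emb.vector(g) for g in batch.positives])
    neg = np.array([emb.vector(g) for g in batch.negatives])
    loss = 0.0
    if len(pos):
        loss -= float(np.sum(np.log(_sigma(pos @ xu))))
    if len(neg):
        loss -= float(np.sum(np.log(_sigma(-(neg @ xu)))))
    return loss


class GeneEmbedder:
    """Learn contrastive gene embeddings from a functional hypergraph.

    sklearn-style: configure in ``__init__``, call :meth:`fit` with a
    :class:`FunctionalHypergraph`, read fitted state off ``embedding_``.

    Parameters
    ----------
    dim : embedding dimensionality (256 per modality by default).
    epochs : full passes of resample-and-update (samples are redrawn each
        epoch).
    n_pos : positives per anchor per epoch; negatives are ``5 * n_pos``.
    learning_rate : Adam step size.
    restart_prob : restart probability q of the random walk.
    tol : Frobenius-norm convergence threshold for the stationary matrix.
    random_state : seed controlling initialization and sampling.
    """

    def __init__(self, dim: int = 256, epochs: int = 50, n_pos: int = 20,
                 learning_rate: float = 1e-3, restart_prob: float = 0.5,
                 tol: float = 1e-6, random_state: int = 0):
        self.dim = dim
        self.epochs = epochs
        self.n_pos = n_pos
        self.learning_rate = learning_rate
        self.restart_prob = restart_prob
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("dim", "epochs", "n_pos", "learning_rate", "restart_prob",
                 "tol", "random_state")}

    def set_params(self, **params) -> "GeneEmbedder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, graph: FunctionalHypergraph) -> "GeneEmbedder":
        universe = graph.universe
        active = [g for g in universe.genes if g not in graph.isolated]
        if len(active) < 2:
            raise ValueError("need at least two non-isolated genes to train")
        rng = np.random.default_rng(self.random_state)
        model = build_transition_matrix(graph, self.restart_prob)
        S = stationary_matrix(model, tol=self.tol)  # column u = profile of u

        n = len(universe)
        X = rng.normal(scale=1.0 / np.sqrt(self.dim), size=(n, self.dim))
        iso_idx = universe.positions(graph.isolated) if graph.isolated else \
            np.array([], dtype=np.int64)
        X[iso_idx] = 0.0
        active_idx = universe.positions(active)

        # Sparse Adam: moments and step counters per gene row; only rows an
        # anchor's samples touch are updated — one step per anchor in a
        # fixed order, skip-gram style, reproducible per seed
        m = np.zeros_like(X)
        v = np.zeros_like(X)
        t_row = np.zeros(n, dtype=np.int64)
        b1, b2, eps = 0.9, 0.999, 1e-8
        losses = []
        for _ in range(self.epochs):
            epoch_loss = 0.0
            for ui in active_idx:
                u = universe.genes[ui]
                prof = StationaryProfile(u, S[:, ui], 0, True)
                pos, neg = sample_neighbors(prof, universe, self.n_pos, rng,
                                            exclude=graph.isolated)
                pi = universe.positions(pos)
                ni = universe.positions(neg)
                xu = X[ui].copy()
                sp = _sigma(X[pi] @ xu)           # want -> 1
                sn = _sigma(X[ni] @ xu)           # want -> 0
                epoch_loss += -float(np.sum(np.log(sp)) + np.sum(np.log1p(-sn)))
                rows = np.unique(np.concatenate([[ui], pi, ni]))
                grad = np.zeros((len(rows), self.dim))
                grad[np.searchsorted(rows, ui)] = \
                    -(1.0 - sp) @ X[pi] + sn @ X[ni]
                np.add.at(grad, np.searchsorted(rows, pi),
                          -np.outer(1.0 - sp, xu))
                np.add.at(grad, np.searchsorted(rows, ni),
                          np.outer(sn, xu))
                t_row[rows] += 1
                tr = t_row[rows][:, None].astype(float)
                m[rows] = b1 * m[rows] + (1 - b1) * grad
                v[rows] = b2 * v[rows] + (1 - b2) * grad ** 2
                X[rows] -= self.learning_rate * (m[rows] / (1 - b1 ** tr)) / \
                    (np.sqrt(v[rows] / (1 - b2 ** tr)) + eps)
            if len(iso_idx):
                X[iso_idx] = 0.0
            losses.append(epoch_loss / len(active_idx))

        self.loss_history_ = losses
        self.embedding_ = EmbeddingMatrix(universe, X, graph.mode, graph.isolated)
        return self

    def transform(self, genes: Iterable[str] | None = None) -> np.ndarray:
        if not hasattr(self, "embedding_"):
            raise RuntimeError("GeneEmbedder is not fitted")
        if genes is None:
            return self.embedding_.vectors
        return np.array([self.embedding_.vector(g) for g in genes])

    def fit_transform(self, graph: FunctionalHypergraph) -> np.ndarray:
        return self.fit(graph).transform()


def train_embeddings(graph: FunctionalHypergraph, dim: int = 256,
                     epochs: int = 50, seed: int = 0, **kwargs) -> EmbeddingMatrix:
    """Functional wrapper over :class:`GeneEmbedder`."""
    return GeneEmbedder(dim=dim, epochs=epochs, random_state=seed,
                        **kwargs).fit(graph).embedding_


def concat_modalities(go_emb: EmbeddingMatrix,
                      expr_emb: EmbeddingMatrix) -> EmbeddingMatrix:
    """Joint representation [x_ontology, x_expression] per gene."""
    if go_emb.universe.genes != expr_emb.universe.genes:
        a, b = set(go_emb.universe.genes), set(expr_emb.universe.genes)
        raise ValueError(
            f"universe mismatch; symmetric difference: {sorted(a ^ b)[:10]}")
    vectors = np.hstack([go_emb.vectors, expr_emb.vectors])
    return EmbeddingMatrix(go_emb.universe, vectors, "concat",
                           go_emb.isolated | expr_emb.isolated)


def write_embedding_table(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Tab-delimited table: gene id then the vector components."""
    with open(path, "w") as fh:
        for g, row in zip(emb.universe.genes, emb.vectors):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_embedding_table(path: str | Path,
                         modality: str = "expression") -> EmbeddingMatrix:
    genes, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vectors = np.array(rows)
    iso = frozenset(g for g, r in zip(genes, vectors)
                    if not np.any(r))
    return EmbeddingMatrix(GeneUniverse(genes), vectors, modality, iso)
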