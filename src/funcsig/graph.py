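"""Weighted functional hypergraphs of genes and random walks with restart.

Genes are nodes; each hyperedge connects the gene set of one annotation term
(ontology mode) or one expression-derived differential gene set (expression
mode).  Edge weights are information content in bits, so rare, specific
annotations dominate the walk.  The stationary distribution of a random walk
with restart from a source gene measures functional proximity and drives
positive/negative sampling for contrastive embedding training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneUniverse",
    "Hyperedge",
    "FunctionalHypergraph",
    "TransitionModel",
    "StationaryProfile",
    "ic_weight_ontology",
    "size_weight_expression",
    "build_transition_matrix",
    "random_walk_restart",
    "stationary_matrix",
    "sample_neighbors",
]


class GeneUniverse:
    """Ordered collection of unique gene identifiers with a gene<->index map."""

    def __init__(self, genes: Iterable[str]):
        genes = list(genes)
        if not genes:
            raise ValueError("universe must contain at least one gene")
        seen = set()
        for g in genes:
            if not g:
                raise ValueError("gene identifiers must be non-empty strings")
            if g in seen:
                raise ValueError(f"duplicate gene identifier: {g!r}")
            seen.add(g)
        self.genes: list[str] = genes
        self.index: dict[str, int] = {g: i for i, g in enumerate(genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def __iter__(self):
        return iter(self.genes)

    def positions(self, genes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index[g] for g in genes), dtype=np.int64)


@dataclass
class Hyperedge:
    """One annotation term or differential gene set.

    ``children`` lists ids of more specific terms (ontology mode only) and is
    used when computing information-content weights; ``weight`` is in bits.
    """

    id: str
    members: frozenset[str]
    children: frozenset[str] = field(default_factory=frozenset)
    weight: float | None = None

    def __post_init__(self):
        self.members = frozenset(self.members)
        self.children = frozenset(self.children)
        if not self.members:
            raise ValueError(f"hyperedge {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class FunctionalHypergraph:
    """Gene universe plus weighted hyperedges, with incidence bookkeeping."""

    def __init__(self, universe: GeneUniverse, edges: Sequence[Hyperedge],
                 mode: str = "expression"):
        if mode not in ("ontology", "expression"):
            raise ValueError(f"unknown mode: {mode!r}")
        if not edges:
            raise ValueError("hypergraph needs at least one hyperedge")
        for e in edges:
            extra = e.members - set(universe.genes)
            if extra:
                raise ValueError(
                    f"edge {e.id!r} has members outside the universe: {sorted(extra)[:5]}")
        self.universe = universe
        self.edges = list(edges)
        self.mode = mode
        covered = set()
        for e in edges:
            covered.update(e.members)
        self.isolated: frozenset[str] = frozenset(set(universe.genes) - covered)

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def incidence(self) -> np.ndarray:
        """Binary |V| x |E| membership matrix H."""
        H = np.zeros((len(self.universe), len(self.edges)))
        for j, e in enumerate(self.edges):
            H[self.universe.positions(e.members), j] = 1.0
        return H

    def degrees(self) -> np.ndarray:
        """d(u) = sum of weights of edges containing u."""
        w = np.array([_require_weight(e) for e in self.edges])
        return self.incidence() @ w


def _require_weight(e: Hyperedge) -> float:
    if e.weight is None:
        raise ValueError(f"edge {e.id!r} has no weight assigned")
    if e.weight < 0:
        raise ValueError(f"edge {e.id!r} has negative weight {e.weight}")
    return e.weight


def _descendant_closure(edges: Sequence[Hyperedge]) -> dict[str, set[str]]:
    """For each edge id, the set of descendant edge ids present in the
    collection plus the edge itself.  Raises on cycles, naming one."""
    by_id = {e.id: e for e in edges}
    closure: dict[str, set[str]] = {}
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(eid: str, stack: list[str]) -> set[str]:
        if state.get(eid) == 1:
            return closure[eid]
        if state.get(eid) == 0:
            cycle = stack[stack.index(eid):] + [eid]
            raise ValueError(f"cycle detected among hyperedges: {' -> '.join(cycle)}")
        state[eid] = 0
        stack.append(eid)
        out = {eid}
        for cid in by_id[eid].children:
            if cid in by_id:  # children outside the collection are ignored
                out |= visit(cid, stack)
        stack.pop()
        state[eid] = 1
        closure[eid] = out
        return out

    for e in edges:
        visit(e.id, [])
    return closure


def ic_weight_ontology(edges: Sequence[Hyperedge]) -> list[Hyperedge]:
    """Assign information-content weights to ontology-term hyperedges.

    The frequency of a term is the total membership of the term and its
    in-collection descendants over the total membership of all terms;
    w(e) = -log2(frequency).  The collection root (descendant mass equal to
    the total) gets weight 0.
    """
    if not edges:
        raise ValueError("empty edge collection")
    by_id = {e.id: e for e in edges}
    closure = _descendant_closure(edges)
    total = sum(len(e) for e in edges)
    out = []
    for e in edges:
        mass = sum(len(by_id[c]) for c in closure[e.id])
        w = -np.log2(mass / total)
        out.append(Hyperedge(e.id, e.members, e.children, max(w, 0.0)))
    return out


def size_weight_expression(edges: Sequence[Hyperedge]) -> list[Hyperedge]:
    """Assign size-based information-content weights, w(e) = -log2(|e|/Σ|e'|)."""
    if not edges:
        raise ValueError("empty edge collection")
    for e in edges:
        if e.children:
            raise ValueError(f"expression-mode edge {e.id!r} must not have children")
    total = sum(len(e) for e in edges)
    return [Hyperedge(e.id, e.members, frozenset(), -float(np.log2(len(e) / total)))
            for e in edges]


@dataclass
class TransitionModel:
    """Row-stochastic random-walk transition matrix with restart probability."""

    matrix: np.ndarray
    restart_prob: float
    universe: GeneUniverse
    isolated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0.0 < self.restart_prob <= 1.0):
            raise ValueError("restart probability must lie in (0, 1]")


def build_transition_matrix(graph: FunctionalHypergraph,
                            restart_prob: float = 0.5) -> TransitionModel:
    """Two-step hypergraph walk: pick an incident edge with probability
    proportional to its weight, then a member of that edge uniformly.

    B(u,v) = Σ_e w(e) · H(u,e)/d(u) · H(v,e)/|e|; self-transitions allowed.
    """
    H = graph.incidence()
    w = np.array([_require_weight(e) for e in graph.edges])
    sizes = np.array([len(e) for e in graph.edges], dtype=float)
    d = H @ w
    iso = np.array([g in graph.isolated for g in graph.universe.genes])
    dead = (d <= 0) & ~iso
    if dead.any():
        bad = [g for g, b in zip(graph.universe.genes, dead) if b][:5]
        raise ValueError(f"genes with zero degree outside the isolated set: {bad}")
    d_safe = np.where(d > 0, d, 1.0)
    # B = (H/d) diag(w) (H/|e|)^T
    B = (H / d_safe[:, None]) @ ((w / sizes)[None, :] * H).T
    B[iso, :] = 0.0
    return TransitionModel(B, restart_prob, graph.universe, graph.isolated)


@dataclass
class StationaryProfile:
    """Stationary visiting distribution of a restart walk from one gene."""

    source: str
    distribution: np.ndarray
    iterations: int
    converged: bool


def _iterate(B: np.ndarray, S0: np.ndarray, q: float, tol: float,
             max_iter: int) -> tuple[np.ndarray, int, float]:
    S = S0.copy()
    for it in range(1, max_iter + 1):
        S_next = (1.0 - q) * (B.T @ S) + q * S0
        resid = float(np.linalg.norm(S_next - S))
        S = S_next
        if resid < tol:
            return S, it, resid
    return S, max_iter, resid


def random_walk_restart(model: TransitionModel, source: str,
                        tol: float = 1e-6, max_iter: int = 10_000) -> StationaryProfile:
    """Power-iterate s <- (1-q) B^T s + q a_u until the 2-norm of the change
    drops below ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    idx = model.universe.index[source]
    a = np.zeros(len(model.universe))
    a[idx] = 1.0
    s, iters, resid = _iterate(model.matrix, a[:, None], model.restart_prob,
                               tol, max_iter)
    if resid >= tol:
        raise RuntimeError(
            f"random walk from {source!r} did not converge in {max_iter} "
            f"iterations (last residual {resid:.3e})")
    return StationaryProfile(source, s.ravel(), iters, True)


def stationary_matrix(model: TransitionModel, tol: float = 1e-6,
                      max_iter: int = 10_000) -> np.ndarray:
    """Stationary distributions for all sources at once; column u is the
    profile of gene u.  Convergence in Frobenius norm of successive change."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = len(model.universe)
    S0 = np.eye(n)
    S, iters, resid = _iterate(model.matrix, S0, model.restart_prob, tol, max_iter)
    if resid >= tol:
        raise RuntimeError(
            f"stationary matrix did not converge in {max_iter} iterations "
            f"(last residual {resid:.3e})")
    return S


def sample_neighbors(profile: StationaryProfile, universe: GeneUniverse,
                     n_pos: int, seed: int | np.random.Generator,
                     neg_ratio: int = 5, eps: float = 1e-12,
                     exclude: Iterable[str] = ()) -> tuple[list[str], list[str]]:
    """Draw positive neighbors N(u) proportional to the stationary distribution
    and negatives R(u) inversely proportional, at |R| = neg_ratio * |N|.

    The source gene (and any ``exclude`` genes, e.g. isolated ones) never
    appears in either set.  Sampling is with replacement.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(profile.distribution, dtype=float)
    mask = np.ones(len(universe), dtype=bool)
    mask[universe.index[profile.source]] = False
    for g in exclude:
        mask[universe.index[g]] = False
    cand = np.flatnonzero(mask)
    if cand.size == 0:
        raise ValueError("no candidate genes to sample from")
    p_pos = s[cand]
    if p_pos.sum() <= 0:
        p_pos = np.ones_like(p_pos)
    p_pos = p_pos / p_pos.sum()
    p_neg = 1.0 / (s[cand] + eps)
    p_neg = p_neg / p_neg.sum()
    genes = np.asarray(universe.genes, dtype=object)
    pos = rng.choice(cand, size=n_pos, replace=True, p=p_pos)
    neg = rng.choice(cand, size=neg_ratio * n_pos, replace=True, p=p_neg)
    return list(genes[pos]), list(genes[neg])
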