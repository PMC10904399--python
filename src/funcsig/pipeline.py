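"""End-to-end orchestration: embeddings -> signature vectors -> Siamese
training -> per-context candidate lists -> consensus ranking -> recall.

The entry point :func:`run_cotarget_pipeline` consumes a
:class:`~funcsig.fixtures.CoTargetFixture` (or any equivalently shaped real
data), trains one Siamese ensemble per perturbagen type with fold splits by
compound, scores every (compound, target, context) combination with the
model that held that compound out, and aggregates per-context lists into a
consensus target ranking per compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding import GeneEmbedder
from .fixtures import CoTargetFixture
from .graph import FunctionalHypergraph, GeneUniverse, Hyperedge, \
    size_weight_expression
from .ranking import CandidateList, ConsensusRanking, consensus_aggregate, \
    recall_at_percent
from .siamese import CoTargetClassifier, PairExample, balanced_pair_sampling, \
    compound_kfold
from .signature import SignatureEmbedder, SignatureVector

logger = logging.getLogger(__name__)

__all__ = ["CoTargetRun", "build_signature_vectors", "run_cotarget_pipeline"]


@dataclass
class CoTargetRun:
    """Everything the co-target pipeline produced."""

    rankings: dict[str, ConsensusRanking]
    recall_at_5: float
    candidate_lists: dict[str, list[CandidateList]]
    models: dict[str, CoTargetClassifier]       # per perturbagen type
    sig_embedder: SignatureEmbedder
    pair_scores: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)                   # type -> (probs, labels)


def train_fixture_embedder(fixture: CoTargetFixture, dim: int = 32,
                           epochs: int = 20, seed: int = 0
                           ) -> SignatureEmbedder:
    """Expression-modality embeddings trained on the fixture's pathways as
    hyperedges."""
    uni = GeneUniverse(fixture.universe)
    edges = size_weight_expression(
        [Hyperedge(f"pw:{t}", members) for t, members in
         sorted(fixture.pathways.items())])
    graph = FunctionalHypergraph(uni, edges, mode="expression")
    emb = GeneEmbedder(dim=dim, epochs=epochs, random_state=seed).fit(graph)
    return SignatureEmbedder(expression=emb.embedding_)


def build_signature_vectors(fixture: CoTargetFixture,
                            embedder: SignatureEmbedder
                            ) -> tuple[dict[tuple[str, str], SignatureVector],
                                       dict[tuple[str, str, str], SignatureVector]]:
    """Aggregate every fixture signature; compounds keyed (id, cell line),
    genetic signatures keyed (gene, perturbagen type, cell line)."""
    compound_vecs = {(s.perturbagen_id, s.cell_line): embedder.embed(s)
                     for s in fixture.compound_signatures}
    genetic_vecs = {(s.perturbagen_id, s.perturbagen_type, s.cell_line):
                    embedder.embed(s) for s in fixture.genetic_signatures}
    return compound_vecs, genetic_vecs


def _positive_pairs(fixture: CoTargetFixture, compound_vecs, genetic_vecs,
                    ptype: str) -> list[PairExample]:
    pairs = []
    for c, targets in sorted(fixture.annotations.items()):
        for t in sorted(targets):
            for cl in fixture.cell_lines:
                ckey, gkey = (c, cl), (t, ptype, cl)
                if ckey in compound_vecs and gkey in genetic_vecs:
                    pairs.append(PairExample(
                        compound_vecs[ckey].vector, genetic_vecs[gkey].vector,
                        1, c, t, cl, ptype))
    return pairs


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def run_cotarget_pipeline(fixture: CoTargetFixture, seed: int = 0,
                          embed_dim: int = 32, embed_epochs: int = 20,
                          hidden1: int = 64, hidden2: int = 16,
                          epochs: int = 60, n_models: int = 3,
                          n_folds: int = 5,
                          embedder: SignatureEmbedder | None = None
                          ) -> CoTargetRun:
    """Train, score held-out, rank, and evaluate recall at the top 5%.

    Signature vectors are L2-normalized before pairing.  Folds split by
    compound; negatives for a fold's training pairs are sampled only from
    that fold's training compounds, so no validation compound influences
    training in any role.  Candidate lists come from the fold model that
    held the scored compound out; consensus pools all (cell line,
    perturbagen type) contexts by normalized rank.
    """
    if embedder is None:
        embedder = train_fixture_embedder(fixture, embed_dim, embed_epochs, seed)
    compound_vecs, genetic_vecs = build_signature_vectors(fixture, embedder)
    targets = sorted(fixture.pathways)
    compounds = sorted(fixture.annotations)

    candidate_scores: dict[tuple[str, str, str], dict[str, float]] = {}
    models: dict[str, CoTargetClassifier] = {}
    pair_scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def balanced_for(positives: list[PairExample], pool: set[str],
                     sample_seed: int) -> list[PairExample]:
        out: list[PairExample] = []
        for ci, cl in enumerate(fixture.cell_lines):
            pos_cl = [p for p in positives if p.cell_line == cl]
            if not pos_cl:
                continue
            cvecs = {c: _unit(compound_vecs[(c, cl)].vector) for c in pool
                     if (c, cl) in compound_vecs}
            out.extend(balanced_pair_sampling(
                pos_cl, cvecs, seed=sample_seed + ci,
                annotations=fixture.annotations))
        return out

    def to_xy(pairs: list[PairExample]) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([[p.compound_vec, p.gene_vec] for p in pairs])
        return X, np.array([p.label for p in pairs])

    ptypes = sorted({s.perturbagen_type for s in fixture.genetic_signatures})
    for pi, ptype in enumerate(ptypes):
        positives = [
            PairExample(_unit(p.compound_vec), _unit(p.gene_vec), 1,
                        p.compound_id, p.target_gene, p.cell_line, ptype)
            for p in _positive_pairs(fixture, compound_vecs, genetic_vecs,
                                     ptype)]
        if not positives:
            continue

        # full-data model kept for downstream use / persistence
        X_all, y_all = to_xy(balanced_for(positives, set(compounds),
                                          seed + 1000 * pi))
        models[ptype] = CoTargetClassifier(
            hidden1=hidden1, hidden2=hidden2, epochs=epochs,
            n_models=n_models, random_state=seed + pi).fit(X_all, y_all)

        # held-out scoring: each compound is scored by the fold model that
        # had it on the validation side
        ho_probs: list[np.ndarray] = []
        ho_labels: list[np.ndarray] = []
        pos_ids = [p.compound_id for p in positives]
        for fi, (tr, va) in enumerate(
                compound_kfold(pos_ids, n_folds, seed + 17 + pi)):
            tr_c = {pos_ids[i] for i in tr}
            va_c = {pos_ids[i] for i in va}
            X_tr, y_tr = to_xy(balanced_for(
                [p for p in positives if p.compound_id in tr_c], tr_c,
                seed + 2000 * pi + 10 * fi))
            clf = CoTargetClassifier(
                hidden1=hidden1, hidden2=hidden2, epochs=epochs,
                n_models=n_models, random_state=seed + 100 * pi + fi)
            clf.fit(X_tr, y_tr)
            va_pairs = balanced_for(
                [p for p in positives if p.compound_id in va_c], va_c,
                seed + 3000 * pi + 10 * fi)
            X_va, y_va = to_xy(va_pairs)
            ho_probs.append(clf.decision_scores(X_va))
            ho_labels.append(y_va)
            for c in sorted(va_c):
                for cl in fixture.cell_lines:
                    if (c, cl) not in compound_vecs:
                        continue
                    cvec = _unit(compound_vecs[(c, cl)].vector)
                    gmat = np.stack([_unit(genetic_vecs[(t, ptype, cl)].vector)
                                     for t in targets])
                    Xc = np.stack([np.broadcast_to(cvec, gmat.shape), gmat],
                                  axis=1)
                    scores = clf.decision_scores(Xc)
                    candidate_scores[(c, cl, ptype)] = dict(zip(targets, scores))
        pair_scores[ptype] = (np.concatenate(ho_probs),
                              np.concatenate(ho_labels))

    candidate_lists: dict[str, list[CandidateList]] = {c: [] for c in compounds}
    for (c, cl, ptype), scores in sorted(candidate_scores.items()):
        candidate_lists[c].append(CandidateList(
            c, list(scores.items()), cl, ptype))
    rankings = {c: consensus_aggregate(lists)
                for c, lists in candidate_lists.items() if lists}
    recall = recall_at_percent(rankings, fixture.annotations, 5.0)
    return CoTargetRun(rankings, recall, candidate_lists, models,
                       embedder, pair_scores)
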