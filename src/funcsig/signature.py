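"""Weighted aggregation of a gene set into a single signature vector.

Experimental gene signatures carry noise genes unrelated to the perturbed
pathway.  Each member gene's average cosine similarity to the rest of the set
is z-scored against that gene's genome-wide similarity background, separately
per modality; the weight w_u = min(max(z_ont, z_expr, 0), 1) then discounts
genes that look no more similar to the set than to the genome at large.  The
signature vector is the weighted mean (1/|G|) Σ w_u x_u of the concatenated
per-gene embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingMatrix, concat_modalities

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SignatureVector",
    "within_set_similarity",
    "zscore_vs_genome",
    "gene_weight",
    "aggregate_signature",
    "SignatureEmbedder",
]


@dataclass
class GeneSignature:
    """A perturbation-derived gene set with its assay metadata."""

    genes: frozenset[str]
    perturbagen_id: str = ""
    perturbagen_type: str = "compound"  # compound | shRNA | cDNA
    cell_line: str = ""
    tas: float | None = None  # Transcriptional Activity Score, provided metadata
    signature_id: str = ""

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("signature gene set must be non-empty")
        if self.perturbagen_type not in ("compound", "shRNA", "cDNA"):
            raise ValueError(f"unknown perturbagen type {self.perturbagen_type!r}")
        if self.tas is not None and self.tas < 0:
            raise ValueError("TAS must be non-negative")


@dataclass
class GeneWeightRecord:
    gene: str
    r_ontology: float
    r_expression: float
    z_ontology: float
    z_expression: float
    weight: float


@dataclass
class SignatureVector:
    """Aggregated signature embedding plus its per-gene weight ledger."""

    vector: np.ndarray
    per_gene: list[GeneWeightRecord] = field(default_factory=list)
    perturbagen_id: str = ""
    perturbagen_type: str = "compound"
    cell_line: str = ""


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    return np.divide(vectors, norms, out=np.zeros_like(vectors), where=norms > 0)


def within_set_similarity(gene: str, sig: GeneSignature,
                          emb: EmbeddingMatrix) -> float:
    """Average cosine of one member against the whole set (self included)."""
    if gene not in sig.genes:
        raise ValueError(f"{gene!r} is not a member of the signature")
    members = sorted(sig.genes)
    U = _unit_rows(np.array([emb.vector(g) for g in members]))
    xu = U[members.index(gene)]
    return float(np.mean(U @ xu))


class _Background:
    """Genome-wide cosine background moments per gene, computed once.

    mean_u and sd_u are over cos(x_u, x_v) for all v != u in the universe;
    cosines against zero vectors count as 0.
    """

    def __init__(self, emb: EmbeddingMatrix):
        U = emb.unit_vectors()
        n = U.shape[0]
        if n < 3:
            raise ValueError("background needs a universe of at least 3 genes")
        C = U @ U.T
        self_cos = np.diag(C).copy()
        row_sum = C.sum(axis=1) - self_cos
        row_sq = (C ** 2).sum(axis=1) - self_cos ** 2
        self.mean = row_sum / (n - 1)
        var = row_sq / (n - 1) - self.mean ** 2
        self.sd = np.sqrt(np.maximum(var, 0.0))


def zscore_vs_genome(gene: str, r: float, emb: EmbeddingMatrix,
                     background: _Background | None = None) -> float:
    """Z-score a within-set similarity against the gene's genome background."""
    bg = background if background is not None else _Background(emb)
    i = emb.universe.index[gene]
    if bg.sd[i] == 0:
        logger.info("zero background sd for %s; z set to 0", gene)
        return 0.0
    return float((r - bg.mean[i]) / bg.sd[i])


def gene_weight(z_ontology: float, z_expression: float) -> float:
    """Clamp the better modality z-score into [0, 1]."""
    return float(min(max(z_ontology, z_expression, 0.0), 1.0))


class SignatureEmbedder:
    """Turn gene signatures into weighted consensus vectors.

    Accepts one embedding per modality; with a single modality the weight is
    driven by that modality's z-score alone and the output vector lives in
    that modality's space.  Background moments are computed once per modality
    and reused across signatures.
    """

    def __init__(self, ontology: EmbeddingMatrix | None = None,
                 expression: EmbeddingMatrix | None = None):
        mods = {}
        if ontology is not None:
            mods["ontology"] = ontology
        if expression is not None:
            mods["expression"] = expression
        if not mods:
            raise ValueError("at least one modality embedding is required")
        first = next(iter(mods.values()))
        for m in mods.values():
            if m.universe.genes != first.universe.genes:
                raise ValueError("modalities must share the same gene universe")
        self.modalities = mods
        self.universe = first.universe
        self._backgrounds = {k: _Background(m) for k, m in mods.items()}
        self._units = {k: m.unit_vectors() for k, m in mods.items()}
        if len(mods) == 2:
            self.concat = concat_modalities(mods["ontology"], mods["expression"])
        else:
            self.concat = first

    def embed(self, sig: GeneSignature) -> SignatureVector:
        present = sorted(g for g in sig.genes if g in self.universe)
        dropped = len(sig.genes) - len(present)
        if dropped:
            logger.info("signature %s: dropped %d genes outside the universe",
                        sig.perturbagen_id or sig.signature_id, dropped)
        if not present:
            raise ValueError("signature has no genes in the embedding universe")
        idx = self.universe.positions(present)
        G = len(present)

        r_by_mod: dict[str, np.ndarray] = {}
        z_by_mod: dict[str, np.ndarray] = {}
        for name, U in self._units.items():
            sub = U[idx]
            r = (sub @ sub.T).mean(axis=1)  # includes the self term
            bg = self._backgrounds[name]
            sd = bg.sd[idx]
            z = np.where(sd > 0, (r - bg.mean[idx]) / np.where(sd > 0, sd, 1.0), 0.0)
            # zero block in this modality: the other modality decides
            zero_block = ~np.any(self.modalities[name].vectors[idx], axis=1)
            z = np.where(zero_block, -np.inf, z)
            r_by_mod[name] = r
            z_by_mod[name] = z

        z_ont = z_by_mod.get("ontology", np.full(G, -np.inf))
        z_expr = z_by_mod.get("expression", np.full(G, -np.inf))
        weights = np.clip(np.maximum.reduce([z_ont, z_expr, np.zeros(G)]), 0.0, 1.0)
        if not np.any(weights > 0):
            logger.warning("signature %s: all weights zero; falling back to "
                           "unweighted mean", sig.perturbagen_id or sig.signature_id)
            weights = np.ones(G)

        vec = (weights[:, None] * self.concat.vectors[idx]).sum(axis=0) / G
        records = [GeneWeightRecord(
            g,
            float(r_by_mod.get("ontology", np.zeros(G))[k]),
            float(r_by_mod.get("expression", np.zeros(G))[k]),
            float(z_ont[k]), float(z_expr[k]), float(weights[k]))
            for k, g in enumerate(present)]
        return SignatureVector(vec, records, sig.perturbagen_id,
                               sig.perturbagen_type, sig.cell_line)


def aggregate_signature(sig: GeneSignature,
                        ontology: EmbeddingMatrix | None = None,
                        expression: EmbeddingMatrix | None = None) -> SignatureVector:
    """One-shot wrapper over :class:`SignatureEmbedder` for a single signature."""
    return SignatureEmbedder(ontology, expression).embed(sig)
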