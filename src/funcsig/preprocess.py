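"""Expression preprocessing and signature selection.

Raw counts go through log2(x+1), quantile normalization against the pooled
sorted-mean reference, and per-gene z-scoring across samples.  Differential
gene sets per sample take the top/bottom 100 ranked genes that also pass
|Z| >= 2; those sets become the hyperedges of the expression-modality
hypergraph.  For perturbation collections, one exemplar signature per
(perturbagen, cell line) is retained — the one with the highest
Transcriptional Activity Score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signature import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "log2_transform",
    "quantile_normalize",
    "zscore_rows",
    "preprocess_expression",
    "differential_gene_set",
    "exemplar_by_tas",
]

_STAGES = ("raw", "log2", "quantile", "zscored")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix tagged with its processing stage."""

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def _advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        if _STAGES.index(stage) <= _STAGES.index(self.stage):
            raise ValueError(f"cannot move from stage {self.stage!r} to {stage!r}")
        return ExpressionMatrix(values, stage)


def log2_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); the pseudocount guards zero counts."""
    if (mat.values < 0).any().any():
        raise ValueError("counts must be non-negative")
    return mat._advance(np.log2(mat.values + 1.0), "log2")


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the pooled reference distribution.

    The reference is the mean of the column-sorted values; ties within a
    column receive the average of the reference values they span.
    """
    X = mat.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    values = pd.DataFrame(out, index=mat.values.index,
                          columns=mat.values.columns)
    return mat._advance(values, "quantile")


def zscore_rows(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples; constant genes become 0 (logged)."""
    X = mat.values.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.info("%d constant gene rows z-scored to 0", constant.sum())
    Z = np.divide(X - mean, sd, out=np.zeros_like(X), where=sd > 0)
    return mat._advance(pd.DataFrame(Z, index=mat.values.index,
                                     columns=mat.values.columns), "zscored")


def preprocess_expression(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Full pipeline: log2 -> quantile normalization -> per-gene z-score."""
    return zscore_rows(quantile_normalize(log2_transform(mat)))


def differential_gene_set(sample_z: pd.Series, rank_cut: int = 100,
                          z_cut: float = 2.0) -> tuple[set[str], set[str]]:
    """Up/down differential gene sets for one sample's z-score vector.

    A gene is up-regulated when it ranks in the top ``rank_cut`` by Z AND
    has Z >= z_cut; down-regulation is the mirror image.  Ranking ties are
    broken by gene id for reproducibility.
    """
    s = pd.Series(sample_z)
    order_desc = sorted(s.index, key=lambda g: (-s[g], g))
    up = {g for g in order_desc[:rank_cut] if s[g] >= z_cut}
    order_asc = sorted(s.index, key=lambda g: (s[g], g))
    down = {g for g in order_asc[:rank_cut] if s[g] <= -z_cut}
    return up, down


def exemplar_by_tas(signatures: list[GeneSignature]) -> list[GeneSignature]:
    """Keep one signature per (perturbagen, cell line): the highest-TAS one,
    ties broken by signature id."""
    for s in signatures:
        if s.tas is None:
            raise ValueError(
                f"signature {s.signature_id or s.perturbagen_id!r} has no TAS")
    groups: dict[tuple[str, str], GeneSignature] = {}
    for s in signatures:
        key = (s.perturbagen_id, s.cell_line)
        cur = groups.get(key)
        if cur is None or (s.tas, _tie(s)) > (cur.tas, _tie(cur)):
            groups[key] = s
    return [groups[k] for k in sorted(groups)]


def _tie(s: GeneSignature) -> str:
    return s.signature_id
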