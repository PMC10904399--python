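"""Consensus target ranking and constrained logistic model fusion.

Per-context prediction lists (one per cell line and perturbagen type) are
pooled by normalized rank O_g/n, keeping each gene's best (minimum) rank —
the consensus ranking.  Rank and activity-profile features feed a logistic
model whose weights are constrained non-negative so the fused probability is
monotone in every evidence channel (guilt-by-association), trained with
per-class sample weights 1/n_p and 1/n_n that balance a heavily imbalanced
label set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateList",
    "ConsensusRanking",
    "ActivityMatrix",
    "consensus_aggregate",
    "odds_ratio_feature",
    "logit_features",
    "max_profile_correlation",
    "NonNegativeLogisticRegression",
    "lr_fit",
    "lr_predict",
    "balanced_metrics",
    "weighted_curve_areas",
    "recall_at_percent",
    "export_network",
]


class CandidateList:
    """Ranked target candidates for one compound in one assay context.

    Entries are sorted by decreasing probability, ties broken by gene id;
    the normalized rank of the gene at (1-based) position O_g is O_g/n.
    """

    def __init__(self, compound_id: str, entries: Sequence[tuple[str, float]],
                 cell_line: str = "", perturbagen_type: str = ""):
        if not entries:
            raise ValueError("candidate list must not be empty")
        genes = [g for g, _ in entries]
        if len(set(genes)) != len(genes):
            raise ValueError("genes must be unique within a candidate list")
        self.compound_id = compound_id
        self.cell_line = cell_line
        self.perturbagen_type = perturbagen_type
        self.entries = sorted(entries, key=lambda e: (-e[1], e[0]))
        self.n = len(self.entries)

    def normalized_ranks(self) -> list[tuple[str, float]]:
        return [(g, (i + 1) / self.n)
                for i, (g, _) in enumerate(self.entries)]


@dataclass
class ConsensusRanking:
    """Deduplicated candidate list pooled across contexts by normalized rank."""

    compound_id: str
    entries: list[tuple[str, float]]  # (gene, normalized rank), non-decreasing

    def rank_of(self, gene: str) -> float | None:
        for g, r in self.entries:
            if g == gene:
                return r
        return None


def consensus_aggregate(lists: Sequence[CandidateList]) -> ConsensusRanking:
    """Pool normalized ranks across lists; each gene keeps its first (best)
    occurrence, i.e. its minimum normalized rank."""
    if not lists:
        raise ValueError("need at least one candidate list")
    compound = lists[0].compound_id
    for cl in lists:
        if cl.compound_id != compound:
            raise ValueError("all lists must belong to the same compound")
    pooled: list[tuple[str, float]] = []
    for cl in lists:
        pooled.extend(cl.normalized_ranks())
    pooled.sort(key=lambda e: (e[1], e[0]))  # stable; ties by gene id
    seen: set[str] = set()
    entries = []
    for g, r in pooled:
        if g not in seen:
            seen.add(g)
            entries.append((g, r))
    return ConsensusRanking(compound, entries)


def odds_ratio_feature(r: float) -> float:
    """Odds-ratio transform x = (1-r)/r of a normalized rank r in (0, 1]."""
    if r <= 0:
        raise ValueError("normalized rank must be positive")
    return (1.0 - r) / r


def logit_features(probs: np.ndarray, clip: float = 1e-6) -> np.ndarray:
    """Logits of base-model probabilities (clipped away from 0 and 1), the
    feature representation used when fusing models."""
    p = np.clip(np.asarray(probs, dtype=float), clip, 1.0 - clip)
    return np.log(p / (1.0 - p))


@dataclass
class ActivityMatrix:
    """Compound x assay activity profiles with per-target reference compounds."""

    values: pd.DataFrame  # compounds x assays; NaN = not measured
    reference_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for gene, refs in self.reference_map.items():
            missing = [c for c in refs if c not in self.values.index]
            if missing:
                raise ValueError(
                    f"reference compounds for {gene!r} absent from matrix: {missing}")


def max_profile_correlation(query: str, target: str,
                            mat: ActivityMatrix,
                            min_shared: int = 3) -> float:
    """Best Pearson correlation between the query compound's activity profile
    and any reference compound of the target; NaN when no usable reference."""
    refs = mat.reference_map.get(target, [])
    if not refs:
        logger.info("no reference compounds for target %s; feature missing", target)
        return float("nan")
    qv = mat.values.loc[query]
    best = -np.inf
    for ref in refs:
        rv = mat.values.loc[ref]
        shared = qv.notna() & rv.notna()
        if shared.sum() < min_shared:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = float(np.corrcoef(qv[shared], rv[shared])[0, 1])
        if np.isfinite(q):
            best = max(best, q)
    if not np.isfinite(best):
        logger.info("insufficient shared assays for (%s, %s); feature missing",
                    query, target)
        return float("nan")
    return best


class NonNegativeLogisticRegression:
    """Logistic regression with non-negative weights and class-balancing.

    Minimizes the per-class-weighted negative log-likelihood (positives
    weighted 1/n_p, negatives 1/n_n) plus an L2 penalty lambda*||w||^2 on the
    weights (not the intercept), subject to w >= 0 so the fitted probability
    is monotone non-decreasing in every feature.  The penalty strength is
    chosen by seeded stratified inner cross-validation over ``lambda_grid``.
    """

    def __init__(self, lambda_grid: Sequence[float] | None = None,
                 cv: int = 5, random_state: int = 0):
        self.lambda_grid = lambda_grid
        self.cv = cv
        self.random_state = random_state

    _param_names = ("lambda_grid", "cv", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "NonNegativeLogisticRegression":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _sample_weights(y: np.ndarray) -> np.ndarray:
        n_p, n_n = y.sum(), (1 - y).sum()
        return np.where(y == 1, 1.0 / n_p, 1.0 / n_n)

    @staticmethod
    def _fit_penalized(X: np.ndarray, y: np.ndarray, lam: float
                       ) -> tuple[np.ndarray, float]:
        n, d = X.shape
        sw = NonNegativeLogisticRegression._sample_weights(y)

        def objective(theta):
            w, b = theta[:d], theta[d]
            z = np.clip(X @ w + b, -30, 30)
            p = 1.0 / (1.0 + np.exp(-z))
            nll = -np.sum(sw * (y * np.log(p + 1e-12)
                                + (1 - y) * np.log(1 - p + 1e-12)))
            grad_z = sw * (p - y)
            grad = np.concatenate([X.T @ grad_z + 2 * lam * w,
                                   [grad_z.sum()]])
            return nll + lam * np.dot(w, w), grad

        theta0 = np.zeros(d + 1)
        bounds = [(0.0, None)] * d + [(None, None)]
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        return res.x[:d], float(res.x[d])

    def fit(self, X: np.ndarray, y: Sequence[int]
            ) -> "NonNegativeLogisticRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        grid = list(self.lambda_grid) if self.lambda_grid is not None else \
            [10.0 ** k for k in range(-3, 4)]

        if not np.any(X):
            warnings.warn("all-zero feature matrix; fitting intercept-only model")
            self.coef_ = np.zeros(X.shape[1])
            self.intercept_ = 0.0
            self.lambda_ = grid[0]
            self.classes_ = np.array([0, 1])
            self.n_features_in_ = X.shape[1]
            return self

        if len(grid) > 1:
            skf = StratifiedKFold(n_splits=min(self.cv, int(y.sum()),
                                               int((1 - y).sum())),
                                  shuffle=True, random_state=self.random_state)
            scores = []
            for lam in grid:
                fold_nll = []
                for tr, va in skf.split(X, y):
                    if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                        continue
                    w, b = self._fit_penalized(X[tr], y[tr], lam)
                    z = np.clip(X[va] @ w + b, -30, 30)
                    p = np.clip(1 / (1 + np.exp(-z)), 1e-12, 1 - 1e-12)
                    sw = self._sample_weights(y[va])
                    fold_nll.append(-np.sum(sw * (y[va] * np.log(p) +
                                                  (1 - y[va]) * np.log(1 - p))))
                scores.append(np.mean(fold_nll) if fold_nll else np.inf)
            best_lam = grid[int(np.argmin(scores))]
        else:
            best_lam = grid[0]

        self.coef_, self.intercept_ = self._fit_penalized(X, y, best_lam)
        self.lambda_ = best_lam
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(self.decision_function(X), -30, 30)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def lr_fit(features: np.ndarray, labels: Sequence[int],
           lambda_grid: Sequence[float] | None = None,
           seed: int = 0) -> NonNegativeLogisticRegression:
    """Functional wrapper over :class:`NonNegativeLogisticRegression`."""
    return NonNegativeLogisticRegression(lambda_grid,
                                         random_state=seed).fit(features, labels)


def lr_predict(model: NonNegativeLogisticRegression,
               x: np.ndarray) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    p = model.predict_proba(x[None, :] if single else x)[:, 1]
    return float(p[0]) if single else p


def balanced_metrics(tp: float, fp: float, tn: float, fn: float,
                     n_p: int, n_n: int) -> dict[str, float]:
    """Classification metrics after reweighting counts to an effective 1:1
    class balance: TP and FN are scaled by 1/n_p, FP and TN by 1/n_n."""
    if n_p <= 0 or n_n <= 0:
        raise ValueError("both class sizes must be positive")
    if tp + fn > n_p or fp + tn > n_n:
        raise ValueError("counts inconsistent with class sizes")
    TP, FN = tp / n_p, fn / n_p
    FP, TN = fp / n_n, tn / n_n
    precision = TP / (TP + FP) if TP + FP > 0 else 0.0
    recall = TP / (TP + FN) if TP + FN > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if precision + recall > 0 else 0.0
    denom = np.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = (TP * TN - FP * FN) / denom if denom > 0 else 0.0
    return {"tp": TP, "fp": FP, "tn": TN, "fn": FN,
            "precision": precision, "recall": recall, "f1": f1, "mcc": float(mcc)}


def weighted_curve_areas(labels: Sequence[int],
                         scores: Sequence[float]) -> dict[str, float]:
    """ROC and precision-recall areas under 1/n_p, 1/n_n sample weighting."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    sw = NonNegativeLogisticRegression._sample_weights(y)
    return {"roc_auc": float(roc_auc_score(y, s, sample_weight=sw)),
            "pr_auc": float(average_precision_score(y, s, sample_weight=sw))}


def recall_at_percent(rankings: Mapping[str, ConsensusRanking],
                      known: Mapping[str, set[str] | Sequence[str]],
                      percent: float = 5.0) -> float:
    """Fraction of compounds with a known target at normalized consensus rank
    <= percent/100 (strict boundary: rank 0.051 misses the top 5%)."""
    cutoff = percent / 100.0
    hits = total = 0
    missing = 0
    for compound, targets in known.items():
        ranking = rankings.get(compound)
        if ranking is None:
            missing += 1
            continue
        total += 1
        targets = set(targets)
        if any(g in targets and r <= cutoff for g, r in ranking.entries):
            hits += 1
    if missing:
        logger.info("recall_at_percent: %d compounds without rankings excluded",
                    missing)
    if total == 0:
        raise ValueError("no compounds with rankings to evaluate")
    return hits / total


def export_network(predictions: pd.DataFrame, path: str | Path,
                   prob_threshold: float = 0.8,
                   rank_threshold: float = 0.05) -> dict:
    """Write the predicted compound-target network as a tab-delimited edge
    list plus a JSON summary sidecar.

    ``predictions`` needs columns compound_id, target_gene, probability,
    normalized_rank; an edge is kept when probability > ``prob_threshold``
    and normalized_rank <= ``rank_threshold``.
    """
    required = {"compound_id", "target_gene", "probability", "normalized_rank"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions missing columns: "
                         f"{sorted(required - set(predictions.columns))}")
    kept = predictions[(predictions.probability > prob_threshold) &
                       (predictions.normalized_rank <= rank_threshold)]
    path = Path(path)
    kept.to_csv(path, sep="\t", index=False)
    summary = {"n_edges": int(len(kept)),
               "n_compounds": int(kept.compound_id.nunique()),
               "n_targets": int(kept.target_gene.nunique()),
               "prob_threshold": prob_threshold,
               "rank_threshold": rank_threshold}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(summary, indent=2))
    return summary
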