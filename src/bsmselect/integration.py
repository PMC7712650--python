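"""Fusion of MRMR filter weights and SVM wrapper weights.

Two fusion rules are provided.  The legacy linear score is the convex
combination ``SL_i = delta * w_i + (1 - delta) * |k_i|``.  The quadratic
integration score first min-max normalizes both weight vectors, ranks
each in ascending order (gamma_MR, gamma_SV; 1 = smallest, ties
averaged) and then forms the rank-weighted mean

    SD_i = [beta * gamma_MR_i * w_i^norm + (1-beta) * gamma_SV_i * |k_i|^norm]
           / [beta * gamma_MR_i + (1-beta) * gamma_SV_i]

so the source on which a gene ranks higher automatically receives more
influence.  SD_i always lies in [0, 1] because it is a weighted mean of
two quantities in [0, 1] with strictly positive weights (ranks >= 1).

The tradeoff beta in (0, 1) is either fixed by the user or chosen
empirically by cross-validation (:func:`select_beta`); the selection
procedure here — grid search maximizing mean classification accuracy of
a linear SVM on the top-n SD-ranked genes under stratified 5-fold CV —
is a reconstruction of the original calibration, whose exact protocol
is not published (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .datamodel import ExpressionDataset
from .mrmr import WeightVector, mrmr_weights
from .svm_ranking import svm_weights, train_linear_svm

__all__ = [
    "IntegrationScore",
    "minmax_normalize",
    "sl_score",
    "quadratic_integration",
    "select_beta",
    "DEFAULT_BETA_GRID",
]

DEFAULT_BETA_GRID: tuple = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass
class IntegrationScore:
    gene_ids: List[str]
    w_norm: np.ndarray
    k_norm: np.ndarray
    rank_mr: np.ndarray
    rank_sv: np.ndarray
    sd: np.ndarray
    beta: float


def minmax_normalize(weights: WeightVector) -> WeightVector:
    """Map weights onto [0, 1]: min -> 0, max -> 1.

    A constant vector maps to all zeros (the 0/0 case): a constant
    ranking carries no information.
    """
    w = weights.weights
    span = w.max() - w.min()
    if span == 0:
        norm = np.zeros_like(w)
    else:
        norm = (w - w.min()) / span
    return WeightVector(gene_ids=list(weights.gene_ids), weights=norm)


def sl_score(w: WeightVector, k: WeightVector, delta: float) -> np.ndarray:
    """Legacy linear fusion ``SL = delta * w + (1 - delta) * |k|``."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if len(w) != len(k):
        raise ValueError("weight vectors differ in length")
    return delta * w.weights + (1.0 - delta) * k.weights


def quadratic_integration(
    w_norm: WeightVector, k_norm: WeightVector, beta: float
) -> IntegrationScore:
    """Quadratic integration score from normalized MRMR and SVM weights.

    Ranks are ascending with ties averaged, so each rank is >= 1 and the
    denominator is strictly positive for beta in (0, 1).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if len(w_norm) != len(k_norm):
        raise ValueError("weight vectors differ in length")
    w = w_norm.weights
    k = k_norm.weights
    g_mr = rankdata(w, method="average")
    g_sv = rankdata(k, method="average")
    num = beta * g_mr * w + (1.0 - beta) * g_sv * k
    den = beta * g_mr + (1.0 - beta) * g_sv
    return IntegrationScore(
        gene_ids=list(w_norm.gene_ids),
        w_norm=w,
        k_norm=k,
        rank_mr=g_mr,
        rank_sv=g_sv,
        sd=num / den,
        beta=beta,
    )


def integration_scores(dataset: ExpressionDataset, beta: float, C: float = 1.0) -> IntegrationScore:
    """MRMR weights + SVM weights -> normalize -> quadratic integration."""
    w = minmax_normalize(mrmr_weights(dataset))
    k = minmax_normalize(svm_weights(train_linear_svm(dataset, C=C)))
    return quadratic_integration(w, k, beta)


def select_beta(
    dataset: ExpressionDataset,
    grid: Optional[Sequence[float]] = None,
    n_top: int = 50,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Choose beta by stratified k-fold CV accuracy on the top-n SD genes.

    For each candidate beta the SD scores are computed on the full data,
    the ``n_top`` highest-SD genes are kept, and the mean accuracy of a
    linear SVM over seeded stratified folds is recorded; the beta with
    the highest mean accuracy wins, ties going to the smallest beta.
    """
    grid = list(DEFAULT_BETA_GRID if grid is None else grid)
    if not grid:
        raise ValueError("beta grid is empty")
    if any(not 0.0 < b < 1.0 for b in grid):
        raise ValueError("beta grid values must lie in (0, 1)")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n_top = min(n_top, dataset.N)
    if min(dataset.M1, dataset.M2) < folds:
        raise ValueError(
            f"a class has fewer samples than folds={folds}; use fewer folds"
        )
    if len(grid) == 1:
        return float(grid[0])

    w = minmax_normalize(mrmr_weights(dataset))
    k = minmax_normalize(svm_weights(train_linear_svm(dataset, C=C)))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = dataset.labels

    best_beta, best_ca = None, -np.inf
    for beta in sorted(grid):
        sd = quadratic_integration(w, k, beta).sd
        top = np.argsort(-sd, kind="stable")[:n_top]
        X = dataset.values[top, :].T
        ca = cross_val_score(SVC(kernel="linear", C=C), X, y, cv=cv).mean()
        if ca > best_ca + 1e-12:
            best_ca, best_beta = ca, float(beta)
    return best_beta
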