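"""Linear SVM training and per-gene weight extraction.

A soft-margin linear support vector machine is fit with samples as
observations and genes as features.  The primal weight of gene i is

    k_i = sum_m phi_m y_m x_im

where phi_m are the (nonnegative) dual coefficients, and |k_i| serves
as the gene-ranking score.  Hard-margin behaviour is recovered with a
large regularization constant C on separable data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from sklearn.svm import SVC

from .datamodel import ExpressionDataset
from .mrmr import WeightVector

__all__ = ["SvmModel", "train_linear_svm", "svm_weights"]


@dataclass
class SvmModel:
    """Fitted linear SVM in terms of its dual representation.

    ``phi`` holds one dual coefficient per training sample (zero for
    non-support vectors) and satisfies the KKT conditions
    ``sum_m phi_m y_m = 0`` and ``0 <= phi_m <= C``; ``k`` is the primal
    weight vector over genes.
    """

    gene_ids: List[str]
    phi: np.ndarray
    labels: np.ndarray
    bias: float
    k: np.ndarray
    C: float

    def __post_init__(self) -> None:
        if not np.isclose(np.sum(self.phi * self.labels), 0.0, atol=1e-6):
            raise ValueError("dual coefficients violate sum(phi * y) = 0")
        if (self.phi < -1e-9).any() or (self.phi > self.C + 1e-6).any():
            raise ValueError("dual coefficients outside [0, C]")


def train_linear_svm(
    dataset: ExpressionDataset,
    C: float = 1.0,
    standardize: bool = False,
) -> SvmModel:
    """Fit a soft-margin linear SVM on genes-as-features.

    Deterministic for fixed input (the SMO solver has no random
    initialization for a fixed problem).  ``standardize`` optionally
    z-scores each gene before fitting; default off since expression
    values are already log2/normalized upstream.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    X = dataset.values.T.copy()  # samples x genes
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    # tight solver tolerance: the dual-expansion contract on k is 1e-6
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(X, y)

    phi = np.zeros(dataset.M)
    # dual_coef_ stores y_m * phi_m for support vectors
    phi[clf.support_] = np.abs(clf.dual_coef_[0])
    k = clf.coef_[0]
    return SvmModel(
        gene_ids=list(dataset.gene_ids),
        phi=phi,
        labels=y.astype(float),
        bias=float(clf.intercept_[0]),
        k=np.asarray(k, dtype=float),
        C=C,
    )


def svm_weights(model: SvmModel) -> WeightVector:
    """Per-gene ranking scores |k_i| from a fitted model."""
    return WeightVector(gene_ids=list(model.gene_ids), weights=np.abs(model.k))
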