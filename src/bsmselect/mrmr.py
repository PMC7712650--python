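"""MRMR (maximum relevance, minimum redundancy) weights for continuous data.

Relevance of a gene is its two-group ANOVA F-statistic against the class
labels; redundancy is its average absolute Pearson correlation with the
other genes, computed ignoring class labels.  The MRMR weight is the
quotient of the two, so a gene scores highly when it separates the
classes well *and* carries information not duplicated by other genes.

Also provides the preliminary screen commonly applied before ranking:
an absolute log2 fold-change cutoff combined with a Welch t-test
p-value cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import stats

from .datamodel import ExpressionDataset, GroupSummary

logger = logging.getLogger(__name__)

#: floor used when a denominator (pooled variance, mean correlation)
#: is exactly zero on degenerate input
EPS = 1e-12

__all__ = [
    "WeightVector",
    "f_statistic",
    "f_statistics",
    "pearson_redundancy",
    "mrmr_weights",
    "preliminary_filter",
]


@dataclass
class WeightVector:
    """Nonnegative per-gene scores (MRMR weights, |k| SVM weights, or
    their min-max normalized forms)."""

    gene_ids: List[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.gene_ids),):
            raise ValueError("weights length must match gene_ids")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.gene_ids)


def f_statistics(dataset: ExpressionDataset) -> np.ndarray:
    """Two-group F-statistics for all genes at once.

    For gene i with group means x_bar_i1, x_bar_i2, overall mean x_bar_i
    and group variances S_i1^2, S_i2^2::

        F(i) = [M1 (x_bar_i1 - x_bar_i)^2 + M2 (x_bar_i2 - x_bar_i)^2]
               / {[(M1-1) S_i1^2 + (M2-1) S_i2^2] / (M - 2)}

    which is the one-way two-group ANOVA F (the squared pooled-variance
    two-sample t).  A zero pooled variance with equal group means gives
    F = 0; with unequal means the denominator is floored at ``EPS``.
    """
    if dataset.M < 3:
        raise ValueError("F-statistic needs at least 3 samples")
    gs = GroupSummary.from_dataset(dataset)
    M1, M2, M = gs.M1, gs.M2, dataset.M
    num = M1 * (gs.case_mean - gs.overall_mean) ** 2 + M2 * (
        gs.control_mean - gs.overall_mean
    ) ** 2
    denom = ((M1 - 1) * gs.case_var + (M2 - 1) * gs.control_var) / (M - 2)
    out = np.zeros_like(num)
    zero = denom <= 0
    out[~zero] = num[~zero] / denom[~zero]
    degenerate = zero & (num > 0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero pooled variance but unequal means; "
            "flooring denominator at %.0e", int(degenerate.sum()), EPS,
        )
        out[degenerate] = num[degenerate] / EPS
    return out


def f_statistic(dataset: ExpressionDataset, gene_index: int) -> float:
    """F-statistic of a single gene (see :func:`f_statistics`)."""
    return float(f_statistics(dataset)[gene_index])


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation across samples; zero-variance genes contribute 0."""
    sd = values.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "%d zero-variance gene(s); their correlations set to 0",
            int(zero.sum()),
        )
    safe = values.copy()
    # give flat genes unit variance so corrcoef is finite, then zero them out
    safe[zero] += np.arange(values.shape[1])
    corr = np.corrcoef(safe)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    return corr


def pearson_redundancy(dataset: ExpressionDataset, i: int, j: int) -> float:
    """Pearson correlation between genes *i* and *j* across all samples,
    ignoring class labels.  Zero-variance genes yield 0 (logged)."""
    if i > j:  # canonical order keeps R(i,j) == R(j,i) bit-exact
        i, j = j, i
    xi, xj = dataset.values[i], dataset.values[j]
    if xi.std() == 0 or xj.std() == 0:
        logger.warning("zero-variance gene in correlation (%d, %d); returning 0", i, j)
        return 0.0
    return float(np.corrcoef(xi, xj)[0, 1])


def mrmr_weights(dataset: ExpressionDataset) -> WeightVector:
    """MRMR weight for every gene:  w_i = F(i) / mean_{j != i} |R(i, j)|.

    The mean absolute correlation is over the other N-1 genes; if it is
    exactly zero it is floored at ``EPS`` so the weight stays finite.
    """
    if dataset.N < 2:
        raise ValueError("MRMR redundancy needs at least 2 genes")
    F = f_statistics(dataset)
    corr = _correlation_matrix(dataset.values)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    mean_abs = abs_corr.sum(axis=1) / (dataset.N - 1)
    mean_abs = np.where(mean_abs <= 0, EPS, mean_abs)
    return WeightVector(gene_ids=list(dataset.gene_ids), weights=F / mean_abs)


def preliminary_filter(
    dataset: ExpressionDataset,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> ExpressionDataset:
    """Screen out genes failing the fold-change / t-test prefilter.

    Data are assumed log2 scale, so the fold change of gene i is the
    difference of its group means; a gene is retained when
    ``|x_bar_i1 - x_bar_i2| >= fc_threshold`` and its Welch two-sample
    t-test p-value is below ``p_threshold``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    case = dataset.values[:, dataset.case_mask]
    ctrl = dataset.values[:, dataset.control_mask]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    _, pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    keep = (np.abs(log2fc) >= fc_threshold) & (pvals < p_threshold)
    n_keep = int(keep.sum())
    logger.info("preliminary filter retained %d / %d genes", n_keep, dataset.N)
    if n_keep < 2:
        raise ValueError(
            f"preliminary filter retained {n_keep} gene(s); "
            "relax --fc/--pval thresholds"
        )
    return dataset.subset_genes(np.flatnonzero(keep))
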