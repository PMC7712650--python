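"""Bootstrap subject-sampling inference for gene relevance.

Samples (subjects) are resampled with replacement B times; on each
bootstrap matrix the full MRMR + SVM + quadratic-integration ranking is
recomputed, giving gene i a position P_ib in {1, ..., N} (1 = highest
integration score) and a rank score

    R_ib = (N + 1 - P_ib) / N  in  [1/N, 1].

Within one bootstrap replicate the rank scores are exactly the set
{1/N, 2/N, ..., 1}, whose median and third quartile tend to 0.5 and
0.75 as N grows.  Gene relevance is the one-sided hypothesis that the
gene's rank score exceeds the third quartile Q3 = 0.75; it is tested
with a signed-rank statistic over the B replicates:

    Z_b = 1{R_b > Q3},   r_b = ascending rank of |R_b - Q3|,
    W   = sum_b Z_b r_b.

Under the null (indicator Bernoulli(1/4) independent of the ranks)
E(W) = B(B+1)/8 and V(W) = B(B+1)(2B+1)/32; the standardized W is
referred to a standard normal upper tail and the per-gene p-values are
adjusted with the Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datamodel import ExpressionDataset, GeneResultTable
from .integration import minmax_normalize, quadratic_integration, select_beta
from .mrmr import mrmr_weights
from .svm_ranking import svm_weights, train_linear_svm

logger = logging.getLogger(__name__)

Q3 = 0.75  #: third quartile of the rank-score distribution (fixed constant)

__all__ = [
    "BootstrapRanking",
    "bootstrap_resample",
    "rank_scores",
    "signed_rank_statistic",
    "null_moments",
    "gene_pvalues",
    "hochberg_adjust",
    "bsm_select",
]


@dataclass
class BootstrapRanking:
    """Per-bootstrap gene positions and rank scores.

    ``positions`` is a B x N integer matrix whose rows are permutations
    of 1..N (1 = best); ``rank_scores`` is the matching matrix of
    R_ib = (N + 1 - P_ib) / N.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.positions, dtype=int)
        B, N = P.shape
        expected = np.arange(1, N + 1)
        for b in range(B):
            if not np.array_equal(np.sort(P[b]), expected):
                raise ValueError(f"bootstrap row {b} is not a permutation of 1..{N}")
        self.positions = P

    @property
    def B(self) -> int:
        return self.positions.shape[0]

    @property
    def N(self) -> int:
        return self.positions.shape[1]

    @property
    def rank_scores(self) -> np.ndarray:
        N = self.N
        return (N + 1 - self.positions) / N


def bootstrap_resample(
    dataset: ExpressionDataset,
    seed: Union[int, np.random.Generator],
) -> ExpressionDataset:
    """Draw M subjects (columns) with replacement, keeping their labels.

    Draws leaving fewer than 2 subjects in either class are rejected and
    redrawn (at most 1000 attempts) so downstream group statistics stay
    defined.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    M = dataset.M
    for attempt in range(1000):
        idx = rng.integers(0, M, size=M)
        y = dataset.labels[idx]
        if np.sum(y == 1) >= 2 and np.sum(y == -1) >= 2:
            if attempt > 0:
                logger.debug("bootstrap draw accepted after %d redraws", attempt)
            # suffix sample ids so the resampled dataset stays valid
            sample_ids = [f"{dataset.sample_ids[i]}#{pos}" for pos, i in enumerate(idx)]
            return ExpressionDataset(
                gene_ids=list(dataset.gene_ids),
                sample_ids=sample_ids,
                values=dataset.values[:, idx],
                labels=y,
            )
    raise RuntimeError(
        "1000 bootstrap draws rejected: class sizes too extreme for resampling"
    )


def rank_scores(positions: np.ndarray) -> np.ndarray:
    """Rank scores R = (N + 1 - P) / N for one permutation of 1..N."""
    P = np.asarray(positions, dtype=int)
    N = P.size
    if not np.array_equal(np.sort(P), np.arange(1, N + 1)):
        raise ValueError("positions must be a permutation of 1..N")
    return (N + 1 - P) / N


def signed_rank_statistic(R_i: np.ndarray, q3: float = Q3) -> float:
    """Signed-rank statistic W for one gene's rank scores over B replicates.

    W = sum of the ascending ranks of |R_b - Q3| (ties averaged) over
    the replicates where R_b > Q3; ranges over [0, B(B+1)/2].
    """
    R = np.asarray(R_i, dtype=float)
    if R.size == 0:
        raise ValueError("empty rank-score vector")
    Z = R > q3
    r = rankdata(np.abs(R - q3), method="average")
    return float(np.sum(r[Z]))


def null_moments(B: int) -> Tuple[float, float]:
    """Null mean and variance of W: B(B+1)/8 and B(B+1)(2B+1)/32."""
    if B < 1:
        raise ValueError("B must be >= 1")
    mean = B * (B + 1) / 8.0
    var = B * (B + 1) * (2 * B + 1) / 32.0
    return mean, var


def gene_pvalues(W: np.ndarray, B: int) -> np.ndarray:
    """One-sided (upper-tail) normal-approximation p-values for W.

    Z_i = (W_i - E(W)) / sqrt(V(W)) referred to N(0, 1); the alternative
    is one-sided (rank score above Q3), so p = P(Z > z).
    """
    if B < 30:
        warnings.warn(
            f"normal approximation with B={B} bootstrap replicates is crude; "
            "consider B >= 30",
            stacklevel=2,
        )
    mean, var = null_moments(B)
    z = (np.asarray(W, dtype=float) - mean) / np.sqrt(var)
    return norm.sf(z)


def hochberg_adjust(p: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p-values.

    With ascending order statistics p_(1) <= ... <= p_(N):
    p~_(N) = p_(N) and p~_(i) = min(p~_(i+1), (N - i + 1) * p_(i)),
    capped at 1 and mapped back to the original order.  Rejecting gene i
    at level alpha is equivalent to p~_i <= alpha.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    N = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(N)
    running = np.inf
    for rank_pos in range(N - 1, -1, -1):  # i = N .. 1
        candidate = (N - rank_pos) * p[order[rank_pos]]
        running = min(running, candidate)
        adj_sorted[rank_pos] = min(running, 1.0)
    adj = np.empty(N)
    adj[order] = adj_sorted
    return adj


def _positions_from_sd(sd: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Positions 1..N by descending SD; ties broken by gene id."""
    order = np.lexsort((gene_ids, -sd))
    positions = np.empty(sd.size, dtype=int)
    positions[order] = np.arange(1, sd.size + 1)
    return positions


def bsm_select(
    dataset: ExpressionDataset,
    B: int = 200,
    beta: Union[float, str] = "auto",
    alpha: float = 0.05,
    C: float = 1.0,
    seed: int = 0,
    n_top: int = 50,
    folds: int = 5,
) -> GeneResultTable:
    """End-to-end bootstrap gene selection.

    Pipeline: (optionally select beta on the full data) -> for each of B
    bootstrap matrices: resample subjects, MRMR weights, SVM weights,
    min-max normalize, quadratic integration, rank genes by descending
    SD -> rank scores -> signed-rank W per gene -> normal upper-tail
    p-values -> Hochberg adjustment -> flag genes with adjusted
    p <= alpha.  Fully reproducible for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    if beta == "auto":
        beta_val = select_beta(
            dataset, n_top=n_top, folds=folds,
            seed=int(rng.integers(0, 2**31 - 1)), C=C,
        )
        logger.info("selected beta = %.3f by cross-validation", beta_val)
    else:
        beta_val = float(beta)
        if not 0.0 < beta_val < 1.0:
            raise ValueError("beta must lie in (0, 1)")

    N = dataset.N
    gene_ids = np.asarray(dataset.gene_ids)
    positions = np.empty((B, N), dtype=int)
    sd_sum = np.zeros(N)
    for b in range(B):
        boot = bootstrap_resample(dataset, rng)
        w = minmax_normalize(mrmr_weights(boot))
        k = minmax_normalize(svm_weights(train_linear_svm(boot, C=C)))
        sd = quadratic_integration(w, k, beta_val).sd
        positions[b] = _positions_from_sd(sd, gene_ids)
        sd_sum += sd

    ranking = BootstrapRanking(positions=positions)
    R = ranking.rank_scores  # B x N
    W = np.array([signed_rank_statistic(R[:, i]) for i in range(N)])
    mean, var = null_moments(B)
    z = (W - mean) / np.sqrt(var)
    p = gene_pvalues(W, B)
    adj = hochberg_adjust(p)

    # full-data weights reported for reference alongside the inference
    w_full = mrmr_weights(dataset).weights
    k_full = svm_weights(train_linear_svm(dataset, C=C)).weights

    frame = pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "mrmr_weight": w_full,
            "svm_weight": k_full,
            "integration_score": sd_sum / B,
            "W": W,
            "z_score": z,
            "p_value": p,
            "adj_p_value": adj,
            "selected": adj <= alpha,
        }
    )
    return GeneResultTable(
        frame=frame,
        alpha=alpha,
        B=B,
        beta=beta_val,
        seed=seed,
        meta={"C": C, "n_top": n_top, "folds": folds},
    )
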