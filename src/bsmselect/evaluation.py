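"""Evaluation criteria for a selected, ranked gene set.

Three complementary views:

* sliding-window classification accuracy — windows of ranked genes are
  scored by cross-validated SVM accuracy, so a good ranking shows high
  mean accuracy with a small spread across windows;
* QTL containment — how many selected genes fall entirely inside
  trait-associated QTL intervals, with hypergeometric enrichment
  significance against the genome-wide rate;
* GO coherence — the average pairwise Jaccard distance between the
  genes' ontology term sets (lower = more functionally coherent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .datamodel import AnnotationMap, ExpressionDataset, GenomicInterval

logger = logging.getLogger(__name__)

KERNELS = ("linear", "rbf", "poly", "sigmoid")

__all__ = [
    "WindowConfig",
    "ClassificationSummary",
    "QtlEnrichment",
    "GoDistanceSummary",
    "sliding_window_accuracy",
    "qtl_qstat",
    "qtl_enrichment_pvalue",
    "qtl_enrichment",
    "go_distance",
    "go_average_distance",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window layout over a ranked gene set of size n.

    Window k (k = 1..K) covers ranked positions (k-1)L+1 .. (k-1)L+S,
    with K = floor((n - S) / L).
    """

    n: int
    S: int
    L: int

    def __post_init__(self) -> None:
        if self.S > self.n:
            raise ValueError("window size S cannot exceed gene-set size n")
        if self.L < 1:
            raise ValueError("sliding length L must be >= 1")
        if self.K < 1:
            raise ValueError("configuration yields no complete window")

    @property
    def K(self) -> int:
        return (self.n - self.S) // self.L

    def window_slices(self) -> List[slice]:
        return [slice(k * self.L, k * self.L + self.S) for k in range(self.K)]


@dataclass
class ClassificationSummary:
    accuracies: np.ndarray  # CA_1 .. CA_K
    mean_ca: float
    se_ca: float
    kernel: str
    config: WindowConfig


@dataclass
class QtlEnrichment:
    qstat: int          # distinct selected genes contained in >= 1 QTL
    pair_count: int     # raw (gene, QTL) containment pairs, for transparency
    v: int
    V: int
    N: int
    n: int
    p_value: float


@dataclass
class GoDistanceSummary:
    average_distance: float
    n_pairs: int
    n_unannotated: int
    distances: np.ndarray = field(default_factory=lambda: np.array([]))


def sliding_window_accuracy(
    dataset: ExpressionDataset,
    ranked_genes: Sequence[str],
    config: WindowConfig,
    kernel: str = "linear",
    folds: int = 5,
    seed: int = 0,
    estimator=None,
) -> ClassificationSummary:
    """Mean and spread of cross-validated accuracy over sliding windows.

    Each window's classifier is evaluated by pooling the held-out
    predictions of a seeded stratified k-fold split, so CA_k is the
    exact fraction of correctly classified samples.  The summary is
    mean CA = (sum CA_k)/K and SE = population standard deviation of
    the CA_k (divisor K).  ``estimator`` overrides the SVM (e.g. with a
    baseline classifier) and is cloned per window by scikit-learn.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    if len(ranked_genes) != config.n:
        raise ValueError("ranked gene list length must equal config.n")
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [g for g in ranked_genes if g not in gene_index]
    if missing:
        raise ValueError(f"ranked genes absent from dataset: {missing[:5]}")
    if min(dataset.M1, dataset.M2) < folds:
        raise ValueError("a class has fewer samples than folds")

    rows = np.array([gene_index[g] for g in ranked_genes])
    y = dataset.labels
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cas = []
    for sl in config.window_slices():
        X = dataset.values[rows[sl], :].T
        clf = SVC(kernel=kernel) if estimator is None else estimator
        pred = cross_val_predict(clf, X, y, cv=cv)
        cas.append(accuracy_score(y, pred))
    cas = np.asarray(cas)
    mean_ca = float(cas.mean())
    se_ca = float(np.sqrt(np.mean((cas - mean_ca) ** 2)))  # divisor K
    return ClassificationSummary(
        accuracies=cas, mean_ca=mean_ca, se_ca=se_ca, kernel=kernel, config=config
    )


def qtl_qstat(
    gene_set: Sequence[str],
    gene_coords: Mapping[str, GenomicInterval],
    qtls: Sequence[GenomicInterval],
    return_pairs: bool = False,
):
    """Count distinct genes in the set fully contained in >= 1 QTL.

    Containment is strict: same chromosome, gene start >= QTL start and
    gene stop <= QTL stop.  Genes without coordinates are excluded with
    a warning.  With ``return_pairs`` the raw (gene, QTL) containment
    pair count is returned too.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chromosome, []).append(q)
    covered = 0
    pairs = 0
    for g in gene_set:
        iv = gene_coords.get(g)
        if iv is None:
            logger.warning("gene %s has no coordinates; excluded from Qstat", g)
            continue
        hits = sum(1 for q in by_chrom.get(iv.chromosome, ()) if q.contains(iv))
        pairs += hits
        if hits:
            covered += 1
    if return_pairs:
        return covered, pairs
    return covered


def qtl_enrichment_pvalue(v: int, N: int, V: int, n: int) -> float:
    """Hypergeometric upper-tail enrichment p-value P[Qstat >= v].

    Population: N genes of which V are QTL-covered; a selection of n
    genes containing v covered ones.  p = sum_{u >= v} C(V,u) C(N-V,n-u)
    / C(N,n).
    """
    if not (0 <= v <= n <= N) or not (0 <= V <= N) or v > min(n, V):
        raise ValueError(f"inconsistent counts v={v}, N={N}, V={V}, n={n}")
    return float(hypergeom.sf(v - 1, N, V, n))


def qtl_enrichment(
    gene_set: Sequence[str],
    all_genes: Sequence[str],
    gene_coords: Mapping[str, GenomicInterval],
    qtls: Sequence[GenomicInterval],
) -> QtlEnrichment:
    """Qstat plus its hypergeometric enrichment p-value in one call.

    ``all_genes`` defines the background population (typically every
    gene in the expression matrix).
    """
    v, pairs = qtl_qstat(gene_set, gene_coords, qtls, return_pairs=True)
    V = qtl_qstat(all_genes, gene_coords, qtls)
    N, n = len(all_genes), len(gene_set)
    p = qtl_enrichment_pvalue(v, N, V, n)
    return QtlEnrichment(qstat=v, pair_count=pairs, v=v, V=V, N=N, n=n, p_value=p)


def go_distance(terms_i: frozenset, terms_j: frozenset) -> float:
    """Jaccard distance 1 - |A n B| / |A u B| between two term sets."""
    union = set(terms_i) | set(terms_j)
    if not union:
        raise ValueError("GO distance undefined for two empty term sets")
    inter = set(terms_i) & set(terms_j)
    return 1.0 - len(inter) / len(union)


def go_average_distance(
    gene_set: Sequence[str],
    annotations: AnnotationMap,
) -> GoDistanceSummary:
    """Average pairwise Jaccard distance over annotated genes in the set.

    Unannotated genes (empty term sets) are skipped and counted; the
    average divides by the number of pairs actually used.
    """
    if len(gene_set) < 2:
        raise ValueError("need at least 2 genes")
    annotated = [g for g in gene_set if annotations[g]]
    n_un = len(gene_set) - len(annotated)
    if len(annotated) < 2:
        raise ValueError("fewer than 2 annotated genes in the set")
    dists = []
    for a in range(len(annotated)):
        for b in range(a + 1, len(annotated)):
            dists.append(go_distance(annotations[annotated[a]], annotations[annotated[b]]))
    d = np.asarray(dists)
    return GoDistanceSummary(
        average_distance=float(d.mean()),
        n_pairs=len(dists),
        n_unannotated=n_un,
        distances=d,
    )
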