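"""Core domain types for two-class expression data and genomic annotation.

The central container is :class:`ExpressionDataset`: a genes x samples
matrix of log2-scale expression values with a two-class label vector
(+1 = case, -1 = control).  Samples are treated as i.i.d. subjects drawn
from a population; genes within a subject may be correlated.  All
downstream machinery (MRMR weights, SVM weights, bootstrap inference)
operates on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GroupSummary",
    "GenomicInterval",
    "AnnotationMap",
    "GeneResultTable",
]


class DataFormatError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with two-class labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, length ``N``.
    sample_ids
        Unique sample identifiers, length ``M``.
    values
        ``(N, M)`` float array of log2-scale expression values.
    labels
        Length-``M`` vector with entries in ``{+1, -1}``
        (case / control).
    """

    gene_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        N, M = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (N, M):
            raise DataFormatError(
                f"values shape {self.values.shape} does not match "
                f"({N} genes, {M} samples)"
            )
        if N < 2:
            raise DataFormatError("need at least 2 genes")
        if M < 4:
            raise DataFormatError("need at least 4 samples")
        if len(set(self.gene_ids)) != N:
            raise DataFormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != M:
            raise DataFormatError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise DataFormatError("expression matrix contains missing or non-finite values")
        if not np.isin(self.labels, (-1, 1)).all() or self.labels.shape != (M,):
            raise DataFormatError("labels must be a length-M vector over {+1, -1}")
        if self.M1 < 2 or self.M2 < 2:
            raise DataFormatError("each class needs at least 2 samples")

    @property
    def N(self) -> int:
        return len(self.gene_ids)

    @property
    def M(self) -> int:
        return len(self.sample_ids)

    @property
    def M1(self) -> int:
        """Number of case (+1) samples."""
        return int(np.sum(self.labels == 1))

    @property
    def M2(self) -> int:
        """Number of control (-1) samples."""
        return int(np.sum(self.labels == -1))

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == -1

    def subset_genes(self, indices: Iterable[int]) -> "ExpressionDataset":
        """Return a new dataset restricted to the given gene row indices."""
        idx = np.asarray(list(indices), dtype=int)
        return ExpressionDataset(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            labels=self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GroupSummary:
    """Per-gene sample statistics split by class.

    Means and variances use the usual unbiased sample forms (divisor
    group size minus one).  The overall mean satisfies
    ``x_bar = (M1*x_bar1 + M2*x_bar2) / M``.
    """

    case_mean: np.ndarray
    control_mean: np.ndarray
    overall_mean: np.ndarray
    case_var: np.ndarray
    control_var: np.ndarray
    M1: int
    M2: int

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset) -> "GroupSummary":
        case = ds.values[:, ds.case_mask]
        ctrl = ds.values[:, ds.control_mask]
        return cls(
            case_mean=case.mean(axis=1),
            control_mean=ctrl.mean(axis=1),
            overall_mean=ds.values.mean(axis=1),
            case_var=case.var(axis=1, ddof=1),
            control_var=ctrl.var(axis=1, ddof=1),
            M1=ds.M1,
            M2=ds.M2,
        )

    def covariance(self, ds: ExpressionDataset, i: int, j: int) -> float:
        """Sample covariance between genes *i* and *j* across all samples."""
        return float(np.cov(ds.values[i], ds.values[j], ddof=1)[0, 1])


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on a chromosome.

    Both gene loci and QTL regions use this convention; BED input
    (0-based half-open) is converted on read.
    """

    chromosome: str
    start: int
    stop: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DataFormatError(f"interval {self.id}: start must be >= 1")
        if self.stop < self.start:
            raise DataFormatError(f"interval {self.id}: stop < start")

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully inside this interval (same chromosome)."""
        return (
            self.chromosome == other.chromosome
            and other.start >= self.start
            and other.stop <= self.stop
        )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


class AnnotationMap:
    """Mapping from gene id to a set of ontology term ids.

    ``category`` is one of MF / BP / CC (molecular function, biological
    process, cellular component); genes absent from the mapping look up
    to the empty set.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]], category: str = "BP") -> None:
        if category not in ("MF", "BP", "CC"):
            raise DataFormatError(f"unknown GO category {category!r}")
        self.category = category
        self._map: Dict[str, FrozenSet[str]] = {
            str(g): frozenset(map(str, terms)) for g, terms in mapping.items()
        }

    def __getitem__(self, gene_id: str) -> FrozenSet[str]:
        return self._map.get(gene_id, frozenset())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def genes(self) -> List[str]:
        return sorted(self._map)


RESULT_COLUMNS = [
    "gene_id",
    "mrmr_weight",
    "svm_weight",
    "integration_score",
    "W",
    "z_score",
    "p_value",
    "adj_p_value",
    "selected",
]


@dataclass
class GeneResultTable:
    """Per-gene output of the full selection pipeline.

    Wraps a DataFrame with one row per gene: MRMR weight, SVM weight,
    mean integration score over bootstrap replicates, signed-rank
    statistic W, its z-score, raw and Hochberg-adjusted p-values, and
    the selection flag at the chosen significance level.
    """

    frame: pd.DataFrame
    alpha: float = 0.05
    B: int = 0
    beta: float = float("nan")
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataFormatError(f"result table missing columns: {missing}")
        p = self.frame["p_value"].to_numpy()
        q = self.frame["adj_p_value"].to_numpy()
        if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
            raise DataFormatError("p-values outside [0, 1]")
        if (q < p - 1e-12).any():
            raise DataFormatError("adjusted p-values must dominate raw p-values")

    @property
    def selected_genes(self) -> List[str]:
        sel = self.frame.loc[self.frame["selected"], "gene_id"]
        return list(sel)

    def sorted(self) -> pd.DataFrame:
        """Rows ordered by ascending adjusted p, ties broken by gene id."""
        return self.frame.sort_values(
            ["adj_p_value", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
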