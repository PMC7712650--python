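"""Seeded generators for expression, genomic-interval and GO fixtures.

The expression generator emulates a two-class log2-scale study: samples
are i.i.d. subjects, background genes are Gaussian noise around a
baseline, a small informative set carries a mean shift of Delta
within-group standard deviations in the case class, and optional
redundant blocks share a latent Gaussian factor giving an expected
within-block correlation of rho.  Companion generators lay genes out on
12 chromosomes with QTL intervals covering a chosen fraction of a
designated subset, and draw GO term sets in which a coherent subset
shares a common annotation core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import AnnotationMap, ExpressionDataset, GenomicInterval

N_CHROMOSOMES = 12  # rice karyotype; cosmetic for fixtures
GENE_SPAN = 1000    # bp per simulated gene
GENE_GAP = 500      # bp between adjacent genes
QTL_FLANK = 100     # bp of QTL slack around covered genes; < GENE_GAP so
                    # a QTL never swallows a neighbouring gene

__all__ = [
    "SimulationSpec",
    "simulate_expression",
    "simulate_genome_features",
    "simulate_annotations",
]


@dataclass
class SimulationSpec:
    """Parameters of the two-class expression simulator.

    Attributes
    ----------
    N, M1, M2
        Number of genes, case samples and control samples.
    n_info
        Number of informative genes (the first ``n_info`` gene ids).
    delta
        Case-class mean shift of informative genes, in units of the
        within-group standard deviation ``sigma``.
    n_blocks, block_size, rho
        Redundant blocks of ``block_size`` genes sharing a latent
        factor with loading sqrt(rho), giving expected within-block
        correlation rho; blocks are carved from the background genes
        immediately after the informative set.
    mu0, sigma
        Baseline mean and within-group standard deviation of the
        log2-scale values.
    """

    N: int = 500
    M1: int = 20
    M2: int = 20
    n_info: int = 20
    delta: float = 2.0
    n_blocks: int = 5
    block_size: int = 10
    rho: float = 0.6
    mu0: float = 8.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_info > self.N:
            raise ValueError("n_info cannot exceed N")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_info + self.n_blocks * self.block_size > self.N:
            raise ValueError("blocks overflow the background gene pool")
        if self.M1 < 2 or self.M2 < 2:
            raise ValueError("need at least 2 samples per class")


def simulate_expression(spec: SimulationSpec) -> Tuple[ExpressionDataset, List[str]]:
    """Simulate a dataset; returns it with the informative gene ids."""
    rng = np.random.default_rng(spec.seed)
    N, M = spec.N, spec.M1 + spec.M2
    width = len(str(N))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(N)]
    sample_ids = [f"case{m + 1:03d}" for m in range(spec.M1)] + [
        f"ctrl{m + 1:03d}" for m in range(spec.M2)
    ]
    labels = np.concatenate([np.ones(spec.M1, dtype=int), -np.ones(spec.M2, dtype=int)])

    values = spec.mu0 + spec.sigma * rng.standard_normal((N, M))

    # redundant blocks: latent factor with loading sqrt(rho)
    start = spec.n_info
    for blk in range(spec.n_blocks):
        rows = slice(start + blk * spec.block_size, start + (blk + 1) * spec.block_size)
        factor = rng.standard_normal(M)
        noise = rng.standard_normal((spec.block_size, M))
        values[rows] = spec.mu0 + spec.sigma * (
            np.sqrt(spec.rho) * factor + np.sqrt(1.0 - spec.rho) * noise
        )

    # informative genes: +delta*sigma shift in the case class
    values[: spec.n_info, labels == 1] += spec.delta * spec.sigma

    ds = ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, labels=labels
    )
    return ds, gene_ids[: spec.n_info]


def simulate_genome_features(
    gene_ids: Sequence[str],
    n_qtls: int,
    frac_info_covered: float,
    seed: int = 0,
    subset: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, GenomicInterval], List[GenomicInterval]]:
    """Place genes on 12 chromosomes and QTLs covering part of a subset.

    Genes get non-overlapping 1 kb spans.  A fraction
    ``frac_info_covered`` of ``subset`` (default: the first ~10% of
    ``gene_ids``) is fully contained in QTLs; by construction no other
    gene is contained in any QTL, so Qstat of the subset equals the
    covered count exactly.  Extra QTLs beyond those needed are placed in
    gene-free territory.
    """
    if not 0.0 <= frac_info_covered <= 1.0:
        raise ValueError("frac_info_covered must lie in [0, 1]")
    gene_ids = [str(g) for g in gene_ids]
    if subset is None:
        subset = gene_ids[: max(1, len(gene_ids) // 10)]
    subset = [str(g) for g in subset]
    unknown = set(subset) - set(gene_ids)
    if unknown:
        raise ValueError(f"subset genes not in gene_ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)

    n_cov = int(round(frac_info_covered * len(subset)))
    covered = list(rng.choice(subset, size=n_cov, replace=False)) if n_cov else []
    covered_set = set(covered)
    others = [g for g in gene_ids if g not in covered_set]
    rng.shuffle(others)

    # group covered genes into contiguous runs, one run per QTL
    n_runs = min(n_qtls, n_cov) if n_cov else 0
    if n_cov and n_runs == 0:
        raise ValueError("need at least one QTL to cover genes")
    runs: List[List[str]] = [list(a) for a in np.array_split(covered, n_runs)] if n_runs else []

    coords: Dict[str, GenomicInterval] = {}
    qtls: List[GenomicInterval] = []
    cursors = {f"chr{c + 1}": 1 for c in range(N_CHROMOSOMES)}
    chrom_names = list(cursors)

    def place(gene: str, chrom: str) -> GenomicInterval:
        start = cursors[chrom]
        iv = GenomicInterval(chrom, start, start + GENE_SPAN - 1, gene)
        cursors[chrom] = iv.stop + 1 + GENE_GAP
        coords[gene] = iv
        return iv

    for r, run in enumerate(runs):
        chrom = chrom_names[r % N_CHROMOSOMES]
        placed = [place(g, chrom) for g in run]
        qtls.append(
            GenomicInterval(
                chrom,
                max(1, placed[0].start - QTL_FLANK),
                placed[-1].stop + QTL_FLANK,
                f"qtl{r + 1:03d}",
            )
        )
        # buffer after the QTL so later genes cannot fall inside it
        cursors[chrom] += QTL_FLANK + 1

    for i, g in enumerate(others):
        place(g, chrom_names[(len(runs) + i) % N_CHROMOSOMES])

    for extra in range(len(runs), n_qtls):
        chrom = chrom_names[extra % N_CHROMOSOMES]
        start = cursors[chrom] + GENE_GAP
        qtls.append(GenomicInterval(chrom, start, start + 5000, f"qtl{extra + 1:03d}"))
        cursors[chrom] = start + 5000 + 1 + GENE_GAP

    return coords, qtls


def simulate_annotations(
    gene_ids: Sequence[str],
    coherent_subset: Sequence[str],
    n_terms: int = 50,
    seed: int = 0,
    core_size: int = 5,
    extra_low: int = 0,
    extra_high: int = 2,
    background_terms: int = 5,
    category: str = "BP",
) -> AnnotationMap:
    """Draw GO term sets with a functionally coherent subset.

    Genes in ``coherent_subset`` share a fixed core of ``core_size``
    terms plus a few random extras, so their expected pairwise Jaccard
    distance sits well below that of background genes, which draw
    ``background_terms`` terms uniformly from the term universe.
    """
    gene_ids = [str(g) for g in gene_ids]
    coherent = {str(g) for g in coherent_subset}
    if not coherent <= set(gene_ids):
        raise ValueError("coherent_subset must be a subset of gene_ids")
    if n_terms < core_size + background_terms:
        raise ValueError("term universe too small")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{t + 1:07d}" for t in range(n_terms)]
    core = terms[:core_size]
    pool = terms[core_size:]

    mapping: Dict[str, set] = {}
    for g in gene_ids:
        if g in coherent:
            n_extra = int(rng.integers(extra_low, extra_high + 1))
            extras = list(rng.choice(pool, size=n_extra, replace=False)) if n_extra else []
            mapping[g] = set(core) | set(extras)
        else:
            mapping[g] = set(rng.choice(terms, size=background_terms, replace=False))
    return AnnotationMap(mapping, category=category)
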