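"""Readers and writers for the plain-text formats the tool touches.

Expression matrices are tab-separated, genes in rows, first row sample
ids, first column gene ids.  Labels are a two-column TSV (sample id,
label), reconciled by sample id rather than position.  Interval files
come in two dialects: ``bed0`` (0-based half-open, standard BED) and
``inclusive1`` (1-based inclusive); everything is converted to the
internal 1-based inclusive convention on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationMap,
    DataFormatError,
    ExpressionDataset,
    GeneResultTable,
    GenomicInterval,
    RESULT_COLUMNS,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_LABEL_TOKENS = {
    "1": 1, "+1": 1, "case": 1,
    "-1": -1, "control": -1, "ctrl": -1,
}


def read_expression(matrix_path: PathLike, labels_path: PathLike) -> ExpressionDataset:
    """Read an expression matrix and a label file into a validated dataset.

    Samples keep the order of the matrix header; labels are matched by
    sample id.  A sample present in one file but not the other is a
    reconciliation error.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate gene ids in {matrix_path}: {dup[:5]}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate sample ids in {matrix_path}: {dup[:5]}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.any().any() or frame.isna().any().any():
        mask = numeric.isna()
        r, c = np.argwhere(mask.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric or missing value at gene {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r} in {matrix_path}"
        )

    labels = _read_labels(labels_path)
    samples = [str(s) for s in frame.columns]
    missing = [s for s in samples if s not in labels]
    if missing:
        raise DataFormatError(
            f"samples in matrix but not in labels file: {missing[:5]}"
        )
    extra = sorted(set(labels) - set(samples))
    if extra:
        raise DataFormatError(
            f"samples in labels file but not in matrix: {extra[:5]}"
        )
    y = np.array([labels[s] for s in samples], dtype=int)
    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=samples,
        values=numeric.to_numpy(dtype=float),
        labels=y,
    )


def _read_labels(path: PathLike) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            sample, token = parts[0].strip(), parts[1].strip().lower()
            if token not in _LABEL_TOKENS:
                raise DataFormatError(
                    f"{path}:{lineno}: label {parts[1]!r} not one of "
                    "1/-1/case/control"
                )
            if sample in out:
                raise DataFormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            out[sample] = _LABEL_TOKENS[token]
    return out


def read_intervals(path: PathLike, dialect: str = "bed0") -> List[GenomicInterval]:
    """Read a 4-column interval file (chrom, start, stop, id).

    ``dialect='bed0'`` treats coordinates as 0-based half-open [s, e) and
    converts to [s+1, e]; ``dialect='inclusive1'`` takes them verbatim.
    """
    if dialect not in ("bed0", "inclusive1"):
        raise ValueError(f"unknown interval dialect {dialect!r}")
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataFormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, iv_id = parts[0], parts[1], parts[2], parts[3]
            try:
                start, stop = int(s), int(e)
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if dialect == "bed0":
                start, stop = start + 1, stop
            try:
                out.append(GenomicInterval(chrom, start, stop, iv_id))
            except DataFormatError as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_annotations(path: PathLike, category: str = "BP") -> AnnotationMap:
    """Read a 2-3 column (gene, term[, category]) annotation table.

    Duplicate (gene, term) pairs collapse; when a third column is present
    only rows matching *category* are kept.  An empty file yields an empty
    map with a logged warning.
    """
    mapping: Dict[str, set] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{path}:{lineno}: expected >= 2 columns")
            gene, term = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip() and parts[2].strip() != category:
                continue
            mapping.setdefault(gene, set()).add(term)
            n_rows += 1
    if n_rows == 0:
        logger.warning("annotation file %s is empty", path)
    return AnnotationMap(mapping, category=category)


def write_results(table: GeneResultTable, path: PathLike) -> None:
    """Write a result table as TSV, ascending adjusted p then gene id.

    Floats are written with 12 significant digits so a read-back
    round-trips losslessly at that precision.
    """
    ordered = table.sorted()[RESULT_COLUMNS]
    ordered.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: PathLike, alpha: float = 0.05) -> GeneResultTable:
    frame = pd.read_csv(path, sep="\t")
    frame["gene_id"] = frame["gene_id"].astype(str)
    frame["selected"] = frame["selected"].astype(bool)
    return GeneResultTable(frame=frame, alpha=alpha)


def write_expression(ds: ExpressionDataset, matrix_path: PathLike, labels_path: PathLike) -> None:
    """Write a dataset in the same formats :func:`read_expression` accepts."""
    ds.to_frame().to_csv(matrix_path, sep="\t", float_format="%.12g")
    with open(labels_path, "w") as fh:
        for s, y in zip(ds.sample_ids, ds.labels):
            fh.write(f"{s}\t{int(y)}\n")


def write_intervals(intervals: List[GenomicInterval], path: PathLike,
                    dialect: str = "inclusive1") -> None:
    if dialect not in ("bed0", "inclusive1"):
        raise ValueError(f"unknown interval dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            if dialect == "bed0":
                fh.write(f"{iv.chromosome}\t{iv.start - 1}\t{iv.stop}\t{iv.id}\n")
            else:
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.stop}\t{iv.id}\n")


def write_annotations(annotations: AnnotationMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for gene in annotations.genes():
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\t{annotations.category}\n")
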