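"""Expression quantification (FPKM), expressed-gene filtering, and matrix I/O.

The abundance unit throughout the package is FPKM: fragments per kilobase of
gene per million mapped fragments,

    FPKM = 1e9 * F / (N * L)

where ``F`` is the number of fragments assigned to the gene in a sample,
``N`` the sample's total mapped fragments, and ``L`` the gene length in bp.
Each sample is normalised by its own ``N``; there is no between-sample
re-scaling.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "compute_fpkm",
    "filter_expressed",
    "log_transform",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class CountMatrix:
    """Gene-level fragment counts with the metadata FPKM needs.

    Parameters
    ----------
    counts
        genes x samples non-negative integer DataFrame (index = gene IDs,
        columns = sample IDs).
    gene_lengths
        Per-gene length in bp, indexed like ``counts``.
    library_sizes
        Per-sample total mapped fragments. Totals may exceed the column sums
        of ``counts``: not every mapped fragment lands in an annotated gene.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise ValueError(f"missing gene lengths for: {missing[:5]}")
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"missing library sizes for: {missing[:5]}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class ExpressionMatrix:
    """genes x samples FPKM matrix with optional ordinal stage labels.

    ``stages`` maps sample ID -> stage label; the ordered stage vocabulary is
    carried in ``stage_order`` (e.g. ``["NCA", "IML", "AMI"]``) so that stage
    labels can be encoded 0, 1, 2, ... for trait correlations.
    """

    values: pd.DataFrame
    stages: pd.Series | None = None
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.stages is not None:
            self.stages = self.stages.reindex(self.values.columns)
            if self.stages.isna().any():
                missing = self.stages.index[self.stages.isna()].tolist()
                raise ValueError(f"samples without a stage label: {missing[:5]}")
            if not self.stage_order:
                self.stage_order = sorted(self.stages.unique().tolist())
            unknown = set(self.stages) - set(self.stage_order)
            if unknown:
                raise ValueError(f"stage labels outside declared order: {sorted(unknown)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def stage_codes(self) -> pd.Series:
        """Ordinal encoding of the stage labels (first stage = 0)."""
        if self.stages is None:
            raise ValueError("expression matrix has no stage labels")
        code = {s: i for i, s in enumerate(self.stage_order)}
        return self.stages.map(code)

    def subset_stage(self, stage: str) -> pd.DataFrame:
        if self.stages is None:
            raise ValueError("expression matrix has no stage labels")
        if stage not in set(self.stage_order):
            raise ValueError(f"unknown stage label: {stage!r}")
        return self.values.loc[:, self.stages[self.stages == stage].index]


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """FPKM = 1e9 * F / (N * L), per gene and per sample.

    Raises a ``ValueError`` naming the offending gene/sample when a gene
    length or library size is not strictly positive.
    """
    L = counts.gene_lengths.to_numpy(dtype=float)
    N = counts.library_sizes.to_numpy(dtype=float)
    bad_L = np.flatnonzero(L <= 0)
    if bad_L.size:
        raise ValueError(
            "non-positive gene length for gene(s): "
            f"{counts.counts.index[bad_L].tolist()[:5]}"
        )
    bad_N = np.flatnonzero(N <= 0)
    if bad_N.size:
        raise ValueError(
            "non-positive library size for sample(s): "
            f"{counts.counts.columns[bad_N].tolist()[:5]}"
        )
    F = counts.counts.to_numpy(dtype=float)
    fpkm = 1e9 * F / (N[np.newaxis, :] * L[:, np.newaxis])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)
    )


def filter_expressed(
    expr: ExpressionMatrix, min_nonzero_samples: int = 8
) -> ExpressionMatrix:
    """Keep genes detected (FPKM > 0) in strictly more than ``min_nonzero_samples``.

    The strict reading means a gene non-zero in exactly ``min_nonzero_samples``
    samples is dropped. Idempotent. Warns (does not fail) if nothing survives.
    """
    n_samples = expr.values.shape[1]
    if min_nonzero_samples >= n_samples:
        raise ValueError(
            f"min_nonzero_samples={min_nonzero_samples} must be below the "
            f"sample count ({n_samples})"
        )
    keep = (expr.values > 0).sum(axis=1) > min_nonzero_samples
    if not keep.any():
        warnings.warn("no gene passes the expression filter", stacklevel=2)
    return ExpressionMatrix(
        expr.values.loc[keep],
        stages=None if expr.stages is None else expr.stages.copy(),
        stage_order=list(expr.stage_order),
    )


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount), the scale used for location tests."""
    return np.log2(expr.values + pseudocount)


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_expression_tsv(
    path,
    stages: pd.Series | None = None,
    stage_order: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV (first column gene IDs, header sample IDs).

    Validates rectangularity and gene-ID uniqueness, reporting the offending
    line number. Transparently accepts gzip (``.gz``).
    """
    with _open_text(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_fields = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ValueError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
            )
        gene_ids.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    index = pd.Index(gene_ids, name=header[0] or "gene_id")
    if index.duplicated().any():
        pos = int(np.flatnonzero(index.duplicated())[0])
        raise ValueError(f"{path}: duplicate gene ID {index[pos]!r} (row {pos + 1})")
    values = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(gene_ids), n_fields - 1),
        index=index,
        columns=header[1:],
    )
    return ExpressionMatrix(
        values,
        stages=stages,
        stage_order=list(stage_order) if stage_order else [],
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write the matrix in the dialect ``read_expression_tsv`` accepts.

    Full ``repr`` float precision, so a write -> read round trip is exact.
    """
    with _open_text(path, "w") as fh:
        name = expr.values.index.name or "gene_id"
        fh.write("\t".join([name, *map(str, expr.values.columns)]) + "\n")
        for gene, row in zip(expr.values.index, expr.values.to_numpy()):
            fh.write("\t".join([str(gene), *(repr(float(v)) for v in row)]) + "\n")
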