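"""Count-matrix container, I/O, low-count filtering and per-batch
size-factor normalization.

The experimental design carried here is a two-factor layout: every
sample has a genotype (``WT`` or ``KO``) and a sequencing batch
(positive integer).  Batches are normalized separately — size factors
are computed within each batch and constrained to geometric mean 1
per batch — and the batch label is then adjusted for at the modeling
level rather than regressed out of the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

VALID_GENOTYPES = ("WT", "KO")


class CountFormatError(ValueError):
    """Raised when a count matrix or its metadata violates the format
    contract (duplicate ids, non-integer entries, missing samples)."""


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts with per-sample genotype and batch.

    Parameters
    ----------
    values
        DataFrame of non-negative integers, genes as rows (index =
        gene ids), samples as columns (column labels = sample ids).
    sample_meta
        DataFrame with columns ``sample_id``, ``genotype`` (``WT`` or
        ``KO``) and ``batch`` (positive integer), one row per sample,
        in the same order as the columns of ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.sample_meta = pd.DataFrame(self.sample_meta).reset_index(drop=True)
        validate_count_matrix(self)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> np.ndarray:
        return self.sample_meta["batch"].to_numpy()

    @property
    def is_ko(self) -> np.ndarray:
        return (self.sample_meta["genotype"] == "KO").to_numpy()


def validate_count_matrix(cm: CountMatrix) -> None:
    v = cm.values
    if v.index.duplicated().any():
        dup = v.index[v.index.duplicated()][0]
        raise CountFormatError(f"duplicate gene id: {dup!r}")
    if v.columns.duplicated().any():
        dup = v.columns[v.columns.duplicated()][0]
        raise CountFormatError(f"duplicate sample id: {dup!r}")
    arr = v.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise CountFormatError("count matrix contains non-numeric entries")
    if np.any(arr < 0):
        g, s = np.argwhere(arr < 0)[0]
        raise CountFormatError(
            f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise CountFormatError(
            f"non-integer count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
        )
    meta = cm.sample_meta
    required = {"sample_id", "genotype", "batch"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise CountFormatError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CountFormatError(f"duplicate sample id in metadata: {dup!r}")
    matrix_samples = list(v.columns)
    meta_samples = list(meta["sample_id"])
    unmatched = set(matrix_samples) ^ set(meta_samples)
    if unmatched:
        raise CountFormatError(
            f"samples present in only one of matrix/metadata: {sorted(unmatched)}"
        )
    if matrix_samples != meta_samples:
        raise CountFormatError("metadata sample order differs from matrix columns")
    bad_geno = ~meta["genotype"].isin(VALID_GENOTYPES)
    if bad_geno.any():
        raise CountFormatError(
            f"invalid genotype {meta.loc[bad_geno, 'genotype'].iloc[0]!r}; "
            f"expected one of {VALID_GENOTYPES}"
        )
    if (meta["batch"].astype(int) < 1).any():
        raise CountFormatError("batch labels must be positive integers")


@dataclass
class SizeFactors:
    """Per-sample multiplicative normalization constants.

    Size factors within each batch have geometric mean 1, so batches
    are normalized separately; ``method`` records how they were
    computed (``median_of_ratios``, ``total_count`` fallback, or
    ``upper_quartile``).
    """

    factors: pd.Series
    method: str = "median_of_ratios"
    per_batch_fallback: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    def to_numpy(self) -> np.ndarray:
        return self.factors.to_numpy()


def read_counts(matrix_path, meta_path, fmt: str = "tsv") -> CountMatrix:
    """Read a count matrix plus sample metadata.

    ``fmt='tsv'`` expects a tab-delimited file, genes as rows, header
    row of sample ids.  ``fmt='mtx'`` expects MatrixMarket coordinate
    format alongside ``<matrix>.rownames.txt`` and
    ``<matrix>.colnames.txt`` files (one id per line).  Metadata is a
    CSV with columns sample_id, genotype, batch; samples are returned
    in metadata order.
    """
    matrix_path = Path(matrix_path)
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    if fmt == "tsv":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    elif fmt == "mtx":
        mat = scipy.io.mmread(matrix_path)
        genes = (
            Path(str(matrix_path) + ".rownames.txt").read_text().split()
        )
        samples = (
            Path(str(matrix_path) + ".colnames.txt").read_text().split()
        )
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        values = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")
    missing = set(meta["sample_id"]) - set(values.columns)
    if missing:
        raise CountFormatError(
            f"metadata sample(s) absent from matrix: {sorted(missing)}"
        )
    extra = set(values.columns) - set(meta["sample_id"])
    if extra:
        raise CountFormatError(
            f"matrix sample(s) absent from metadata: {sorted(extra)}"
        )
    values = values[list(meta["sample_id"])]
    values = values.astype(np.int64, errors="ignore")
    return CountMatrix(values=values, sample_meta=meta)


def write_counts(cm: CountMatrix, matrix_path, meta_path, fmt: str = "tsv") -> None:
    """Write a CountMatrix in the dialect :func:`read_counts` reads."""
    matrix_path = Path(matrix_path)
    if fmt == "tsv":
        cm.values.to_csv(matrix_path, sep="\t")
    elif fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.values.to_numpy())
        scipy.io.mmwrite(str(matrix_path), sparse)
        Path(str(matrix_path) + ".rownames.txt").write_text(
            "\n".join(map(str, cm.gene_ids)) + "\n"
        )
        Path(str(matrix_path) + ".colnames.txt").write_text(
            "\n".join(map(str, cm.sample_ids)) + "\n"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    cm.sample_meta.to_csv(meta_path, index=False)


def filter_low_counts(cm: CountMatrix, threshold: float = 3.0) -> CountMatrix:
    """Drop genes whose across-sample mean count is strictly below
    ``threshold``.

    The boundary is kept: a gene with mean exactly equal to the
    threshold survives ("mean of less than 3" removed).  Idempotent;
    sample metadata untouched.
    """
    means = cm.values.mean(axis=1)
    keep = means >= threshold
    if not keep.any():
        warnings.warn("filter_low_counts removed every gene", stacklevel=2)
    return CountMatrix(values=cm.values.loc[keep].copy(), sample_meta=cm.sample_meta.copy())


def _median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios factors for one batch.

    Reference = geometric mean across samples over genes positive in
    every sample of the batch; returns None-equivalent (raises) if no
    such gene exists.
    """
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no all-positive reference gene")
    sub = counts[positive].astype(float)
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / ref[:, None], axis=0)


def size_factors_per_batch(cm: CountMatrix, method: str = "median_of_ratios") -> SizeFactors:
    """Compute size factors within each batch independently.

    Each batch's factors are rescaled to geometric mean 1, so between-
    batch depth differences are deliberately not absorbed here — they
    belong to the batch intercepts of the count model.  If a batch has
    no gene with all-positive counts, that batch falls back to
    total-count ratios with a warning.  ``method='upper_quartile'``
    uses the within-batch 75th-percentile of nonzero counts instead of
    median-of-ratios.
    """
    if method not in ("median_of_ratios", "upper_quartile"):
        raise ValueError(f"unknown method {method!r}")
    batches = cm.batches
    arr = cm.values.to_numpy()
    factors = np.empty(cm.n_samples, dtype=float)
    fallback: dict = {}
    for b in np.unique(batches):
        idx = np.flatnonzero(batches == b)
        if len(idx) < 2:
            raise ValueError(f"batch {b} has fewer than 2 samples")
        sub = arr[:, idx]
        if method == "upper_quartile":
            s = np.array(
                [np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan
                 for col in sub.T]
            )
            if np.isnan(s).any():
                raise ValueError(f"batch {b} has an all-zero sample")
        else:
            try:
                s = _median_of_ratios(sub)
            except ValueError:
                warnings.warn(
                    f"batch {b}: no all-positive reference gene; "
                    "falling back to total-count ratios",
                    stacklevel=2,
                )
                totals = sub.sum(axis=0).astype(float)
                if np.any(totals <= 0):
                    raise ValueError(f"batch {b} has an all-zero sample")
                s = totals
                fallback[int(b)] = "total_count"
        # geometric mean 1 within the batch
        s = s / np.exp(np.mean(np.log(s)))
        factors[idx] = s
    return SizeFactors(
        factors=pd.Series(factors, index=cm.sample_ids),
        method=method,
        per_batch_fallback=fallback,
    )
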