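"""Expression matrices, sample annotations, gene filtering and the PCA baseline.

The substrate of every downstream step is a genes x samples matrix of FPKM
values (fragments per kilobase of transcript per million mapped reads),
carried as a pandas DataFrame with gene ids on the index and sample ids on
the columns.  Values are log10(FPKM + 1)-transformed before clustering; the
``transformed`` flag records which scale the matrix is on so the transform
cannot be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataFormatError, ParseError, StateError

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "load_annotation",
    "validate_annotation",
    "log_transform",
    "filter_low_expression",
    "pca_gene_selection",
    "REGIONS",
    "DOMAINS",
]

REGIONS = ("A", "P", "L", "R")
DOMAINS = ("D1", "D2", "D3", "D4")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix.

    Parameters
    ----------
    frame : pandas.DataFrame
        Gene ids on the index, sample ids on the columns, numeric body.
    transformed : bool
        False for raw FPKM (all values >= 0), True for log10(FPKM + 1).
    """

    frame: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.frame.index
        cols = self.frame.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataFormatError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataFormatError(f"duplicate sample id: {dup!r}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataFormatError("expression body must be numeric")
        if not np.isfinite(values).all():
            raise DataFormatError("expression matrix contains non-finite values")
        if not self.transformed and (values < 0).any():
            raise DataFormatError("raw FPKM values must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; unknown ids raise KeyError."""
        missing = [g for g in genes if g not in self.frame.index]
        if missing:
            raise KeyError(f"gene(s) not present in matrix: {missing[:5]}")
        return ExpressionMatrix(self.frame.loc[genes].copy(), self.transformed)

    def to_tsv(self, path: str | Path) -> None:
        """Write back in the input dialect (gene id column + sample header)."""
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (optionally gzipped).

    First column = gene ids, header row = sample ids, numeric body.
    Raises :class:`DataFormatError` on duplicate ids and :class:`ParseError`
    (naming the row/column) on a non-numeric cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(f"missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}")
    numeric.index = numeric.index.astype(str)
    return ExpressionMatrix(numeric.astype(float))


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation table (sample_id, section, region, domain)."""
    annot = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "section", "region", "domain"}
    missing = required - set(annot.columns)
    if missing:
        raise DataFormatError(f"annotation missing column(s): {sorted(missing)}")
    annot = annot.set_index("sample_id")
    validate_annotation(annot)
    return annot


def validate_annotation(annot: pd.DataFrame, sample_ids: list[str] | None = None) -> None:
    """Check annotation invariants, optionally against a companion matrix."""
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()][0]
        raise DataFormatError(f"duplicate annotation for sample {dup!r}")
    bad_region = set(annot["region"]) - set(REGIONS)
    if bad_region:
        raise DataFormatError(f"unknown region label(s): {sorted(bad_region)}")
    bad_domain = set(annot["domain"]) - set(DOMAINS)
    if bad_domain:
        raise DataFormatError(f"unknown domain label(s): {sorted(bad_domain)}")
    if (annot["section"].astype(int) < 1).any():
        raise DataFormatError("section indices must be >= 1")
    if sample_ids is not None:
        unannotated = set(sample_ids) - set(annot.index)
        if unannotated:
            raise DataFormatError(f"samples without annotation: {sorted(unannotated)[:5]}")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log10(FPKM + 1) copy of a raw matrix.

    0 maps to 0 and the transform is strictly monotone per cell.  Applying it
    to an already-transformed matrix raises :class:`StateError`.
    """
    if m.transformed:
        raise StateError("matrix is already log10(FPKM + 1)-transformed")
    return ExpressionMatrix(np.log10(m.frame + 1.0), transformed=True)


def filter_low_expression(
    m: ExpressionMatrix,
    fpkm_threshold: float = 1.0,
    min_samples: int = 2,
    var_threshold: float = 0.05,
) -> ExpressionMatrix:
    """Drop low-expression genes from a raw FPKM matrix.

    A gene is kept iff FPKM > ``fpkm_threshold`` (strict) in at least
    ``min_samples`` samples AND the unbiased (n-1) variance of
    log10(FPKM + 1) across samples is strictly greater than
    ``var_threshold``.  Gene order is preserved, so the operation is
    idempotent and commutes with row permutations.
    """
    if m.transformed:
        raise StateError("filter operates on raw FPKM values")
    if m.n_samples < 2:
        raise ValueError("at least two samples are required to filter genes")
    values = m.values
    expressed = (values > fpkm_threshold).sum(axis=1) >= min_samples
    log_values = np.log10(values + 1.0)
    variances = log_values.var(axis=1, ddof=1)
    keep = expressed & (variances > var_threshold)
    return ExpressionMatrix(m.frame.loc[keep].copy(), transformed=False)


def pca_gene_selection(m: ExpressionMatrix, n_top: int = 40) -> list[str]:
    """Select genes with extreme loadings on the first two principal components.

    Samples are the observations and genes the variables; genes are centred
    to zero mean (no unit-variance scaling).  The union of the ``n_top``
    highest- and lowest-loading genes on PC1 and PC2 is returned sorted by
    gene id (at most ``4 * n_top`` unique genes).  The selection is invariant
    to sign flips of either principal axis: negating an axis swaps its top
    and bottom tails, leaving the union unchanged.
    """
    if not m.transformed:
        raise StateError("PCA gene selection expects a log-transformed matrix")
    if 2 * n_top > m.n_genes:
        raise ValueError(f"2 * n_top = {2 * n_top} exceeds gene count {m.n_genes}")
    X = m.values.T  # samples x genes
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(X - X.mean(axis=0))
    selected: set[str] = set()
    genes = np.asarray(m.gene_ids)
    for loadings in pca.components_:
        order = np.argsort(loadings, kind="stable")
        selected.update(genes[order[:n_top]])
        selected.update(genes[order[-n_top:]])
    return sorted(selected)
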