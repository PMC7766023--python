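"""Gene x sample expression matrices and their on-disk formats.

The package's central data object is a non-negative gene x sample matrix
(FPKM-like values or raw counts).  Genes index the rows, samples the
columns, matching the convention of expression tables distributed by GDC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """Non-negative expression values with gene and sample identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Non-negative expression values (counts, FPKM, or transformed).
    genes : list of str
        Row identifiers.
    samples : list of str
        Column identifiers.
    """

    values: np.ndarray
    genes: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n_genes, n_samples = self.values.shape
        if not self.genes:
            self.genes = [f"g{i}" for i in range(n_genes)]
        if not self.samples:
            self.samples = [f"s{j}" for j in range(n_samples)]
        if len(self.genes) != n_genes or len(self.samples) != n_samples:
            raise ValueError("identifier lists do not match matrix shape")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with genes in the index, samples in columns."""
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)),
                   list(map(str, df.columns)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to ``gene_ids`` (order preserved)."""
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows, :], list(gene_ids),
                                list(self.samples))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_mtx(cls, path, genes_path=None, samples_path=None) -> "ExpressionMatrix":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_ids(genes_path) if genes_path else []
        samples = _read_ids(samples_path) if samples_path else []
        return cls(np.asarray(mat, dtype=float), genes, samples)

    def write_mtx(self, path) -> None:
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(self.values))


def _read_ids(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gene_list(path) -> list[str]:
    """Read a one-identifier-per-line gene list."""
    return _read_ids(path)


def write_gene_list(gene_ids, path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
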