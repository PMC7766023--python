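"""Weighted bipartite gene-sample multigraph.

Expression values become integer edge multiplicities: an entry w between
gene i and sample j contributes w parallel edges, i.e. w half-edges to
each endpoint.  These half-edge counts are the counting units of the
topic/cluster probability estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class BipartiteGraph:
    """Gene and sample node sets with integer edge multiplicities.

    ``gene_idx``, ``sample_idx`` and ``mult`` are parallel arrays: edge k
    joins gene ``genes[gene_idx[k]]`` to sample ``samples[sample_idx[k]]``
    with multiplicity ``mult[k]`` (> 0).  Nodes with no surviving edge are
    retained as isolated nodes.
    """

    genes: list[str]
    samples: list[str]
    gene_idx: np.ndarray
    sample_idx: np.ndarray
    mult: np.ndarray

    def __post_init__(self) -> None:
        self.gene_idx = np.asarray(self.gene_idx, dtype=np.int64)
        self.sample_idx = np.asarray(self.sample_idx, dtype=np.int64)
        self.mult = np.asarray(self.mult, dtype=np.int64)
        if not (self.gene_idx.shape == self.sample_idx.shape == self.mult.shape):
            raise ValueError("edge arrays must be parallel")
        if np.any(self.mult <= 0):
            raise ValueError("zero or negative edge multiplicities are not allowed")
        if set(self.genes) & set(self.samples):
            raise ValueError("gene and sample identifier sets must be disjoint")
        gk, sk = self.gene_half_edges(), self.sample_half_edges()
        assert gk.sum() == sk.sum(), "bipartite half-edge conservation violated"

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_edges(self) -> int:
        """Total edge mass E (sum of multiplicities)."""
        return int(self.mult.sum())

    def gene_half_edges(self) -> np.ndarray:
        return np.bincount(self.gene_idx, weights=self.mult,
                           minlength=self.n_genes).astype(np.int64)

    def sample_half_edges(self) -> np.ndarray:
        return np.bincount(self.sample_idx, weights=self.mult,
                           minlength=self.n_samples).astype(np.int64)

    def isolated_nodes(self) -> tuple[list[str], list[str]]:
        """Genes and samples with no incident edge."""
        g = [self.genes[i] for i in np.flatnonzero(self.gene_half_edges() == 0)]
        s = [self.samples[j] for j in np.flatnonzero(self.sample_half_edges() == 0)]
        return g, s

    def to_matrix(self) -> ExpressionMatrix:
        """Dense multiplicity matrix (lossless for integer inputs)."""
        m = np.zeros((self.n_genes, self.n_samples))
        np.add.at(m, (self.gene_idx, self.sample_idx), self.mult)
        return ExpressionMatrix(m, list(self.genes), list(self.samples))

    # ------------------------------------------------------------------ I/O
    def write_edgelist(self, path) -> None:
        pd.DataFrame({
            "gene_id": [self.genes[i] for i in self.gene_idx],
            "sample_id": [self.samples[j] for j in self.sample_idx],
            "multiplicity": self.mult,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_edgelist(cls, path) -> "BipartiteGraph":
        df = pd.read_csv(path, sep="\t")
        genes = sorted(df["gene_id"].astype(str).unique())
        samples = sorted(df["sample_id"].astype(str).unique())
        gpos = {g: i for i, g in enumerate(genes)}
        spos = {s: j for j, s in enumerate(samples)}
        return cls(genes, samples,
                   df["gene_id"].astype(str).map(gpos).to_numpy(),
                   df["sample_id"].astype(str).map(spos).to_numpy(),
                   df["multiplicity"].to_numpy())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes, bipartite="gene")
        g.add_nodes_from(self.samples, bipartite="sample")
        for i, j, w in zip(self.gene_idx, self.sample_idx, self.mult):
            g.add_edge(self.genes[i], self.samples[j], weight=int(w))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


def build_bipartite(expr: ExpressionMatrix, discretize: str = "half_even") -> BipartiteGraph:
    """Build the multigraph from an expression matrix.

    ``discretize`` controls how non-integer weights become multiplicities:
    'half_even' rounds half to even (default, bias-free); 'floor' truncates;
    'exact' requires integer entries.  Entries rounding below 1 create no
    edge; the affected genes/samples stay as isolated nodes.
    """
    if expr.values.size == 0:
        raise ValueError("empty expression matrix")
    if discretize == "half_even":
        w = np.rint(expr.values)
    elif discretize == "floor":
        w = np.floor(expr.values)
    elif discretize == "exact":
        if not np.allclose(expr.values, np.rint(expr.values)):
            raise ValueError("'exact' discretization requires integer entries")
        w = expr.values
    else:
        raise ValueError(f"unknown discretization mode {discretize!r}")
    gi, sj = np.nonzero(w >= 1)
    return BipartiteGraph(list(expr.genes), list(expr.samples),
                          gi, sj, w[gi, sj].astype(np.int64))


def half_edge_counts(graph: BipartiteGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node incident multiplicity totals (gene side, sample side).

    Both sides sum to the edge mass E.
    """
    return graph.gene_half_edges(), graph.sample_half_edges()
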