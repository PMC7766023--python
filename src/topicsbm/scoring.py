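"""Cluster/label agreement scores.

The agreement between inferred sample clusters and annotation labels
(e.g. cancer subtypes) is measured by the normalized mutual information
defined as the harmonic mean of homogeneity h and completeness C:

    h   = 1 - H(C|K)/H(C),   C = 1 - H(K|C)/H(K),   NMI = 2hC/(h+C).

Random clusterings score above zero, increasingly so with more clusters,
so the empirical NMI is normalized by NMI*: the mean NMI of a null model
that keeps the number and sizes of clusters but reshuffles the sample
labels.  NMI/NMI* is set to 1 when both are zero (the single-cluster
layer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def contingency(labels, clusters) -> np.ndarray:
    """Label x cluster count table n_ck from two parallel sequences."""
    labels = pd.Series(list(labels))
    clusters = pd.Series(list(clusters))
    if len(labels) != len(clusters):
        raise ValueError("labels and clusters must be parallel")
    return pd.crosstab(labels, clusters).to_numpy()


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(table: np.ndarray) -> float:
    """NMI of a label x cluster contingency table.

    Conventions: 0 ln 0 = 0; a degenerate label (H(C)=0) gives h = 1; a
    degenerate clustering (H(K)=0) gives C = 1; h = C = 0 gives NMI = 0.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency table must be a non-negative 2-D array")
    n = table.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    n_c = table.sum(axis=1)
    n_k = table.sum(axis=0)
    h_c = _entropy(n_c)
    h_k = _entropy(n_k)

    nz = table > 0
    p = table[nz] / n
    h_c_given_k = float(-(p * np.log(table[nz] / np.broadcast_to(n_k, table.shape)[nz])).sum())
    h_k_given_c = float(-(p * np.log(table[nz] / np.broadcast_to(n_c[:, None], table.shape)[nz])).sum())

    h = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if h + c == 0:
        return 0.0
    return 2.0 * h * c / (h + c)


def nmi_from_labels(labels, clusters) -> float:
    return nmi(contingency(labels, clusters))


def null_nmi(labels, cluster_sizes, reps: int = 100, seed: int = 0) -> float:
    """Mean NMI under fixed-cluster-size label reshuffling (NMI*)."""
    labels = np.asarray(list(labels))
    cluster_sizes = np.asarray(list(cluster_sizes), dtype=int)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cluster_sizes.sum() != labels.size:
        raise ValueError("cluster sizes must sum to the number of labels")
    rng = np.random.default_rng(seed)
    null_clusters = np.repeat(np.arange(cluster_sizes.size), cluster_sizes)
    values = np.empty(reps)
    for r in range(reps):
        values[r] = nmi(contingency(rng.permutation(labels), null_clusters))
    return float(values.mean())


def normalized_nmi(nmi_value: float, nmi_star: float) -> float:
    """NMI/NMI* with the both-zero convention mapping to 1."""
    if nmi_value < 0 or nmi_star < 0:
        raise ValueError("scores must be non-negative")
    if nmi_star == 0:
        if nmi_value == 0:
            return 1.0
        warnings.warn("NMI* is zero with non-zero NMI; normalized score degenerate")
        return float("inf")
    return nmi_value / nmi_star


@dataclass
class ScoreResult:
    """NMI, its reshuffling null, and the normalized ratio for one level."""

    nmi: float
    nmi_star: float
    normalized: float
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return {"nmi": self.nmi, "nmi_star": self.nmi_star,
                "normalized": self.normalized, "reps": self.reps,
                "seed": self.seed}


def score_clustering(labels, clusters, reps: int = 100, seed: int = 0) -> ScoreResult:
    """NMI of a clustering against labels, normalized by its own null."""
    labels = np.asarray(list(labels))
    clusters = np.asarray(list(clusters))
    value = nmi_from_labels(labels, clusters)
    sizes = pd.Series(clusters).value_counts().sort_index().to_numpy()
    star = null_nmi(labels, sizes, reps=reps, seed=seed)
    return ScoreResult(value, star, normalized_nmi(value, star), reps, seed)
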