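"""Probabilistic summaries of a block assignment.

Once genes are grouped into topics and samples into clusters, the graph's
half-edge counts yield two conditional distributions:

    P(topic | sample) = half-edges on the sample coming from the topic
                        / half-edges on the sample
    P(gene | topic)   = half-edges of the gene / half-edges of the topic

plus centered variants used to visualize enrichment and group (subtype,
stage, cluster) aggregations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bigraph import BipartiteGraph


def _topic_array(graph: BipartiteGraph, topics) -> np.ndarray:
    if isinstance(topics, dict):
        missing = [g for g in graph.genes if g not in topics]
        if missing:
            raise ValueError(f"genes without a topic assignment: {missing[:5]}")
        arr = np.array([topics[g] for g in graph.genes], dtype=np.int64)
    else:
        arr = np.asarray(topics, dtype=np.int64)
        if arr.size != graph.n_genes:
            raise ValueError("topic array length does not match gene count")
    return arr


def topic_given_sample(graph: BipartiteGraph, topics) -> pd.DataFrame:
    """Sample x topic mixture matrix P(topic|sample).

    Rows of samples with at least one half-edge sum to 1; zero-degree
    samples get an all-zero row and a warning.
    """
    t = _topic_array(graph, topics)
    n_topics = int(t.max()) + 1
    counts = np.zeros((graph.n_samples, n_topics))
    np.add.at(counts, (graph.sample_idx, t[graph.gene_idx]), graph.mult)
    totals = counts.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} samples have no half-edges; "
                      "their mixture rows are zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(p, index=graph.samples,
                        columns=[f"topic{k}" for k in range(n_topics)])


def gene_given_topic(graph: BipartiteGraph, topics) -> pd.DataFrame:
    """Topic x gene matrix P(gene|topic); empty topics give NaN rows."""
    t = _topic_array(graph, topics)
    n_topics = int(t.max()) + 1
    gene_he = graph.gene_half_edges().astype(float)
    topic_he = np.bincount(t, weights=gene_he, minlength=n_topics)
    p = np.zeros((n_topics, graph.n_genes))
    for k in range(n_topics):
        members = t == k
        if topic_he[k] == 0:
            warnings.warn(f"topic {k} has no half-edges; row undefined")
            p[k, :] = np.nan
        else:
            p[k, members] = gene_he[members] / topic_he[k]
    return pd.DataFrame(p, index=[f"topic{k}" for k in range(n_topics)],
                        columns=graph.genes)


def center(distribution: pd.DataFrame) -> pd.DataFrame:
    """Center P(topic|sample) per topic over all samples.

    Each topic column has its cohort mean subtracted, so columns sum to 0;
    the operation is linear and order-preserving within a topic.
    """
    return distribution - distribution.mean(axis=0)


def aggregate_by_group(distribution: pd.DataFrame, labels,
                       center_groups: bool = False) -> pd.DataFrame:
    """Group x topic means of P(topic|sample).

    ``labels`` maps sample id -> group; samples with missing labels (NaN,
    "nan", "not reported") are dropped for this aggregation only.  With
    ``center_groups`` the mean over groups is subtracted afterwards, giving
    the centered per-stage (or per-subtype) enrichment.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(distribution.index)
    valid = labels.notna() & ~labels.astype(str).str.lower().isin(
        {"nan", "not reported"})
    dropped = int((~valid).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} samples with missing group labels")
    sub = distribution.loc[valid.values]
    grouped = sub.groupby(labels[valid.values].values).mean()
    if center_groups:
        grouped = grouped - grouped.mean(axis=0)
    return grouped


def rank_genes(gene_given_topic_df: pd.DataFrame, topic) -> list[tuple[str, float]]:
    """Genes of one topic sorted by decreasing P(gene|topic).

    Ties break by gene id; only genes with positive probability (i.e.
    members of the topic with expression) appear.  Suitable for export to
    external gene-set enrichment tools.
    """
    key = topic if isinstance(topic, str) else f"topic{topic}"
    if key not in gene_given_topic_df.index:
        raise ValueError(f"no topic {topic!r}")
    row = gene_given_topic_df.loc[key]
    entries = [(g, float(p)) for g, p in row.items() if p > 0]
    if not entries:
        warnings.warn(f"topic {topic!r} is empty")
        return []
    return sorted(entries, key=lambda kv: (-kv[1], kv[0]))


def write_ranked_genes(ranked, path) -> None:
    pd.DataFrame(ranked, columns=["gene_id", "probability"]).to_csv(
        path, sep="\t", index=False)
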