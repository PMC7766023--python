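"""Model/Results interface over the bipartite block model.

`TopicBlockModel` holds the data (an expression matrix or a pre-built
bipartite multigraph) and the preprocessing choices; `fit()` runs MDL
inference and returns a `TopicBlockResults` carrying the hierarchy, the
topic/cluster probability summaries, diagnostics and a text summary, in
the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import blockmodel, preprocess, scoring, survival, topics
from .bigraph import BipartiteGraph, build_bipartite
from .matrix import ExpressionMatrix


class TopicBlockModel:
    """Bipartite gene-sample block model of an expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame or BipartiteGraph
        Gene x sample non-negative expression values, or an already
        discretized multigraph.
    log_transform : bool
        Apply log2(x+1) before discretization (sparsifies the graph).
    discretize : str
        Rounding mode turning weights into edge multiplicities
        ('half_even', 'floor' or 'exact').
    """

    def __init__(self, data, log_transform: bool = False,
                 discretize: str = "half_even"):
        if isinstance(data, BipartiteGraph):
            self.graph = data
            self.expr = None
        else:
            if isinstance(data, pd.DataFrame):
                data = ExpressionMatrix.from_frame(data)
            self.expr = data
            if log_transform:
                data = preprocess.log_transform(data)
            self.graph = build_bipartite(data, discretize=discretize)
        self.log_transformed = log_transform

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TopicBlockModel":
        """Build from a DataFrame with genes in the index, samples in columns."""
        return cls(df, **kwargs)

    def fit(self, n_restarts: int = 10, seed: int = 0,
            config: blockmodel.FitConfig | None = None) -> "TopicBlockResults":
        """Minimize the description length and return the fitted results."""
        cfg = config or blockmodel.FitConfig(n_restarts=n_restarts, seed=seed)
        hierarchy = blockmodel.fit(self.graph, cfg)
        return TopicBlockResults(self, hierarchy, cfg)


class TopicBlockResults:
    """Fitted block hierarchy with probability summaries and diagnostics."""

    def __init__(self, model: TopicBlockModel, hierarchy: blockmodel.BlockHierarchy,
                 config: blockmodel.FitConfig):
        self.model = model
        self.hierarchy = hierarchy
        self.config = config

    # ------------------------------------------------------------ accessors
    @property
    def n_levels(self) -> int:
        return self.hierarchy.n_levels

    def description_length(self, level: int = 0) -> float:
        return self.hierarchy.level(level).sigma

    def clusters(self, level: int = 0) -> dict[str, int]:
        """Sample -> cluster map at the given hierarchy level."""
        return blockmodel.extract_clusters(self.hierarchy, level)

    def topics(self, level: int = 0) -> dict[str, int]:
        """Gene -> topic map at the given hierarchy level."""
        return blockmodel.extract_topics(self.hierarchy, level)

    def topic_given_sample(self, level: int = 0) -> pd.DataFrame:
        return topics.topic_given_sample(self.model.graph, self.topics(level))

    def gene_given_topic(self, level: int = 0) -> pd.DataFrame:
        return topics.gene_given_topic(self.model.graph, self.topics(level))

    def centered_topic_given_sample(self, level: int = 0) -> pd.DataFrame:
        return topics.center(self.topic_given_sample(level))

    def rank_genes(self, topic, level: int = 0):
        return topics.rank_genes(self.gene_given_topic(level), topic)

    # ----------------------------------------------------------- evaluation
    def score_against(self, labels, level: int | None = None,
                      reps: int = 100, seed: int = 0):
        """NMI / NMI* / normalized score of the clusters against labels.

        ``labels`` maps sample id -> annotation.  With ``level=None`` every
        level is scored and a DataFrame is returned (the paper-style
        per-layer score curve); otherwise a single ScoreResult.
        """
        labels = pd.Series(labels)

        def one(level_idx: int) -> scoring.ScoreResult:
            cl = self.clusters(level_idx)
            samples = [s for s in self.hierarchy.samples if s in labels.index]
            return scoring.score_clustering(
                [labels[s] for s in samples], [cl[s] for s in samples],
                reps=reps, seed=seed)

        if level is not None:
            return one(level)
        rows = []
        for lvl in range(self.n_levels):
            res = one(lvl)
            rows.append({"level": lvl,
                         "n_clusters": self.hierarchy.level(lvl).n_clusters,
                         "n_topics": self.hierarchy.level(lvl).n_topics,
                         **res.to_dict()})
        return pd.DataFrame(rows)

    def survival_analysis(self, clinical: pd.DataFrame, topic, level: int = 0):
        """Cox fit of the topic's up-regulation feature on a clinical table.

        ``clinical`` must carry sample_id, duration_days and event columns;
        rows are matched to samples by id.
        """
        pts = self.topic_given_sample(level)
        clin = clinical.set_index("sample_id").loc[
            [s for s in pts.index if s in set(clinical["sample_id"])]]
        up = survival.upregulation_feature(pts.loc[clin.index], topic)
        return survival.cox_fit(clin.reset_index(), up.to_numpy())

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        """Plain-text per-level summary of the fitted hierarchy."""
        buf = io.StringIO()
        g = self.model.graph
        buf.write("Bipartite topic block model\n")
        buf.write("=" * 58 + "\n")
        buf.write(f"genes: {g.n_genes}   samples: {g.n_samples}   "
                  f"edge mass E: {g.total_edges}\n")
        buf.write(f"restarts: {self.config.n_restarts}   seed: {self.config.seed}\n")
        buf.write("-" * 58 + "\n")
        buf.write(f"{'level':>5} {'topics':>8} {'clusters':>9} {'sigma (nats)':>16}\n")
        for lvl in range(self.n_levels):
            level = self.hierarchy.level(lvl)
            buf.write(f"{lvl:>5} {level.n_topics:>8} {level.n_clusters:>9} "
                      f"{level.sigma:>16.2f}\n")
        return buf.getvalue()

    # ------------------------------------------------------------- plotting
    def plot_topic_enrichment(self, labels, level: int = 0, ax=None):
        """Box plot of centered P(topic|sample) grouped by an annotation."""
        import matplotlib.pyplot as plt

        centered = self.centered_topic_given_sample(level)
        labels = pd.Series(labels).reindex(centered.index)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        melted = centered.assign(group=labels.values).melt(
            id_vars="group", var_name="topic", value_name="centered")
        groups = sorted(melted["group"].dropna().unique())
        topics_ = list(centered.columns)
        width = 0.8 / max(len(groups), 1)
        for gi, grp in enumerate(groups):
            sub = melted[melted.group == grp]
            data = [sub[sub.topic == t]["centered"].values for t in topics_]
            positions = np.arange(len(topics_)) + gi * width
            ax.boxplot(data, positions=positions, widths=width * 0.9,
                       label=str(grp))
        ax.set_xticks(np.arange(len(topics_)) + 0.4 - width / 2)
        ax.set_xticklabels(topics_, rotation=45)
        ax.set_ylabel("centered P(topic|sample)")
        ax.axhline(0, color="grey", lw=0.5)
        ax.legend()
        return ax
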