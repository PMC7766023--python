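"""End-to-end orchestration: configuration, staged execution, manifests.

A run takes an expression matrix (and optional clinical/label tables),
applies one gene-selection strategy, builds the bipartite multigraph,
fits the block hierarchy, derives the topic distributions and runs the
toggled analyses (cluster scoring, survival, classification).  Every
artifact is written to the output directory together with a JSON manifest
recording inputs, seeds and per-level description lengths, so a run is
replayable from the manifest alone.
"""

from __future__ import annotations

import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import blockmodel, classifier, preprocess, survival, synthetic, topics
from .bigraph import build_bipartite
from .matrix import ExpressionMatrix, write_gene_list
from .model import TopicBlockModel


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    expression_path: str | None = None
    clinical_path: str | None = None
    labels_path: str | None = None
    output_dir: str = "run_output"
    gene_selection: str = "highly_variable"   # or "tissue_specific"
    n_genes: int = 3000
    tissue_mask_column: str | None = None
    log_transform: bool = True
    n_restarts: int = 10
    max_sweeps: int = 100
    score_clusters: bool = True
    run_survival: bool = False
    run_classifier: bool = False
    survival_topic: int = 0
    classifier_label_column: str = "subtype"
    split_proportions: tuple[float, float, float] = (0.48, 0.32, 0.2)
    hidden_units: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_selection not in {"highly_variable", "tissue_specific", "none"}:
            raise ValueError(f"unknown gene selection {self.gene_selection!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["split_proportions"] = list(self.split_proportions)
        return d


def _derive_seed(master: int, stage: str) -> int:
    """Per-stage seed derived from the master seed; stays below 2**31."""
    import zlib

    return int(np.random.SeedSequence([master, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2**31))


def run(config: RunConfig, expr: ExpressionMatrix | None = None,
        clinical: pd.DataFrame | None = None,
        labels: pd.Series | None = None) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    Inputs may be given in-memory or through the configured paths.  A
    stage failure aborts with the failing stage named; artifacts written
    before the failure are retained.
    """
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": []}
    stage = "load"
    try:
        if expr is None:
            if config.expression_path is None:
                raise ValueError("no expression matrix given")
            expr = ExpressionMatrix.read_tsv(config.expression_path)
        if clinical is None and config.clinical_path:
            clinical = pd.read_csv(config.clinical_path, sep="\t")
        if labels is None and config.labels_path:
            lab = pd.read_csv(config.labels_path, sep="\t")
            labels = lab.set_index("sample_id").iloc[:, 0]
        manifest["stages"]["load"] = {"n_genes": expr.n_genes,
                                      "n_samples": expr.n_samples}

        stage = "select"
        if config.gene_selection == "highly_variable":
            selected = preprocess.select_highly_variable(expr, config.n_genes)
        elif config.gene_selection == "tissue_specific":
            if labels is None or config.tissue_mask_column is None:
                raise ValueError("tissue_specific selection needs labels and "
                                 "tissue_mask_column naming the in-group label")
            mask = np.array([labels.get(s) == config.tissue_mask_column
                             for s in expr.samples])
            scores = preprocess.tissue_specific_scores(expr, mask)
            selected = preprocess.select_tissue_specific(scores, config.n_genes)
        else:
            selected = list(expr.genes)
        expr = expr.subset_genes(selected)
        write_gene_list(selected, out / "selected_genes.txt")
        manifest["outputs"].append("selected_genes.txt")
        manifest["stages"]["select"] = {"n_selected": len(selected)}

        stage = "graph"
        working = preprocess.log_transform(expr) if config.log_transform else expr
        graph = build_bipartite(working)
        graph.write_edgelist(out / "edges.tsv")
        manifest["outputs"].append("edges.tsv")
        manifest["stages"]["graph"] = {"edge_mass": graph.total_edges,
                                       "n_edges": int(graph.mult.size)}

        stage = "fit"
        cfg = blockmodel.FitConfig(n_restarts=config.n_restarts,
                                   seed=_derive_seed(config.seed, "fit"),
                                   max_sweeps=config.max_sweeps)
        model = TopicBlockModel(graph)
        results = model.fit(config=cfg)
        results.hierarchy.write(out / "hierarchy.tsv", out / "hierarchy_meta.json")
        manifest["outputs"] += ["hierarchy.tsv", "hierarchy_meta.json"]
        manifest["stages"]["fit"] = {
            "levels": [{"level": lvl,
                        "sigma": results.description_length(lvl),
                        "n_topics": results.hierarchy.level(lvl).n_topics,
                        "n_clusters": results.hierarchy.level(lvl).n_clusters}
                       for lvl in range(results.n_levels)]}

        stage = "topics"
        pts = results.topic_given_sample(0)
        pgt = results.gene_given_topic(0)
        pts.to_csv(out / "topic_given_sample.tsv", sep="\t", index_label="sample_id")
        pgt.to_csv(out / "gene_given_topic.tsv", sep="\t", index_label="topic")
        topics.center(pts).to_csv(out / "topic_given_sample_centered.tsv",
                                  sep="\t", index_label="sample_id")
        manifest["outputs"] += ["topic_given_sample.tsv", "gene_given_topic.tsv",
                                "topic_given_sample_centered.tsv"]
        manifest["stages"]["topics"] = {"n_topics": pts.shape[1]}

        if config.score_clusters and labels is not None:
            stage = "score"
            table = results.score_against(labels,
                                          seed=_derive_seed(config.seed, "score"))
            table.to_csv(out / "scores.tsv", sep="\t", index=False)
            manifest["outputs"].append("scores.tsv")
            best = table.loc[table["nmi"].idxmax()]
            manifest["stages"]["score"] = {
                "best_level": int(best["level"]), "best_nmi": float(best["nmi"]),
                "best_normalized": float(best["normalized"])}

        if config.run_survival and clinical is not None:
            stage = "survival"
            cox = results.survival_analysis(clinical, config.survival_topic)
            clusters = results.clusters(0)
            clin = clinical[clinical["sample_id"].isin(clusters)].copy()
            clin["cluster"] = clin["sample_id"].map(clusters)
            z = survival.cluster_survival_zscore(
                clin["cluster"], clin, seed=_derive_seed(config.seed, "survival"))
            z.to_csv(out / "cluster_survival.tsv", sep="\t", index=False)
            with open(out / "cox.json", "w") as fh:
                json.dump(cox.to_dict(), fh, indent=2)
            manifest["outputs"] += ["cluster_survival.tsv", "cox.json"]
            manifest["stages"]["survival"] = cox.to_dict()

        if config.run_classifier and labels is not None:
            stage = "classify"
            y = np.array([labels.get(s) for s in pts.index])
            keep = pd.notna(y)
            x = classifier.normalize_design(pts.to_numpy()[keep])
            yk = y[keep]
            tr, va, te = classifier.split(len(yk), config.split_proportions,
                                          seed=_derive_seed(config.seed, "split"))
            mlp = classifier.train_mlp(
                x[tr], yk[tr], x[va], yk[va],
                classifier.MLPConfig(hidden_units=config.hidden_units,
                                     seed=_derive_seed(config.seed, "mlp")))
            report = classifier.evaluate(mlp.predict_proba(x[te]), yk[te],
                                         classes=mlp.classes)
            with open(out / "classifier_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            manifest["outputs"].append("classifier_report.json")
            manifest["stages"]["classify"] = {"accuracy": report.accuracy,
                                              "f1": report.f1,
                                              "auc": report.auc}
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["completed"] = True
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


PRESETS = {
    "tiny": dict(n_samples=60, n_genes=120, n_clusters=2, n_topics=3,
                 depth_mean=300.0),
    "desk": dict(n_samples=300, n_genes=600, n_clusters=4, n_topics=5,
                 depth_mean=1000.0),
}


def make_fixture(preset: str, seed: int, directory) -> pathlib.Path:
    """Write a synthetic dataset (expression + truth + clinical) to disk."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = synthetic.SyntheticConfig(seed=seed, **PRESETS[preset])
    expr, truth = synthetic.generate_dataset(cfg)
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    expr.write_tsv(d / "expression.tsv")
    synthetic.write_truth(truth, d)
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump({**PRESETS[preset], "seed": seed}, fh)
    return d
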