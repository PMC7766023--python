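"""Synthetic expression data with planted topic and cluster structure.

Emulates the generative picture behind topic modeling of RNA-seq: each
sample is a "document" whose transcript counts are drawn from a mixture of
topic-specific gene distributions.  Clusters of samples share a signature
mixture; clinical covariates (tumor stage, survival) are tied to one
driver topic so that every downstream analysis stage has a ground truth.

The defaults define the planted-study conditions used throughout the test
suite; see docs/methods.md for the rationale behind each one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

STAGES = ("i", "ii", "iii", "iv")

#: Weight a cluster's signature mixture puts on its own topic; the rest is
#: spread uniformly over the remaining topics.
SIGNATURE_WEIGHT = 0.6


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Attributes
    ----------
    n_samples, n_genes, n_clusters, n_topics : int
        Matrix shape and planted block counts (``n_topics >= n_clusters``).
    mixture_concentration : float
        Dirichlet concentration of per-sample topic weights around the
        cluster signature.  Large values pin samples to the signature;
        0 degenerates to a one-hot draw from the signature.
    topic_gene_overlap : float
        Fraction of each topic's gene support borrowed from other topics'
        base gene sets; 0 gives disjoint supports.
    depth_mean : float
        Expected total count per sample (Poisson sequencing depth).
    baseline_hazard : float
        Exponential death hazard per day for the low-topic group.
    topic_hazard_ratio : float
        Multiplicative hazard for samples whose driver-topic weight
        exceeds the cohort median.
    censoring_fraction : float
        Target fraction of records censored by independent uniform
        censoring times.
    stage_trend_slope : float
        Strength of the stage trend in the driver topic (per stage step);
        positive in the first subtype, mirrored in the second.
    seed : int
        Master seed; all outputs are reproducible given it.
    """

    n_samples: int = 300
    n_genes: int = 600
    n_clusters: int = 4
    n_topics: int = 5
    mixture_concentration: float = 50.0
    topic_gene_overlap: float = 0.1
    depth_mean: float = 1000.0
    baseline_hazard: float = 1.0 / 1000.0
    topic_hazard_ratio: float = 2.0
    censoring_fraction: float = 0.2
    stage_trend_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_clusters", "n_topics"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_topics < self.n_clusters:
            raise ValueError("n_topics must be >= n_clusters")
        if self.n_topics > self.n_genes:
            raise ValueError("n_topics cannot exceed n_genes")
        if self.n_clusters > self.n_samples:
            raise ValueError("n_clusters cannot exceed n_samples")
        if self.mixture_concentration < 0:
            raise ValueError("mixture_concentration must be >= 0")
        if not 0 <= self.topic_gene_overlap <= 1:
            raise ValueError("topic_gene_overlap must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.censoring_fraction <= 1:
            raise ValueError("censoring_fraction must lie in [0, 1]")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic expression matrix."""

    theta: np.ndarray            # sample x topic mixtures, rows sum to 1
    phi: np.ndarray              # topic x gene distributions, rows sum to 1
    cluster_label: np.ndarray    # int per sample
    subtype_label: np.ndarray    # str per sample (== cluster by default)
    stage_label: np.ndarray | None = None
    survival: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{j}" for j in range(self.theta.shape[0])]


def _cluster_signatures(n_clusters: int, n_topics: int) -> np.ndarray:
    """Signature mixture per cluster: SIGNATURE_WEIGHT on its own topic."""
    sig = np.full((n_clusters, n_topics), (1.0 - SIGNATURE_WEIGHT) / max(n_topics - 1, 1))
    for k in range(n_clusters):
        sig[k, k] = SIGNATURE_WEIGHT if n_topics > 1 else 1.0
    return sig / sig.sum(axis=1, keepdims=True)


def _topic_gene_distributions(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Topic x gene matrix phi with controllably overlapping supports."""
    segments = np.array_split(np.arange(cfg.n_genes), cfg.n_topics)
    phi = np.zeros((cfg.n_topics, cfg.n_genes))
    for t, seg in enumerate(segments):
        support = list(seg)
        n_extra = int(round(cfg.topic_gene_overlap * len(seg)))
        if n_extra > 0:
            others = np.setdiff1d(np.arange(cfg.n_genes), seg)
            extra = rng.choice(others, size=min(n_extra, others.size), replace=False)
            support.extend(extra.tolist())
        support = np.array(sorted(support))
        weights = rng.dirichlet(np.ones(support.size))
        phi[t, support] = weights
    return phi


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a count matrix from planted per-sample topic mixtures.

    Each sample's total count is Poisson(depth_mean); conditional on the
    total, counts are multinomial over genes with probabilities
    ``theta[s] @ phi``.  Returns the matrix and the planted truth
    (mixtures, gene distributions, cluster and subtype labels).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # balanced cluster labels, shuffled
    base = np.repeat(np.arange(cfg.n_clusters),
                     int(np.ceil(cfg.n_samples / cfg.n_clusters)))[: cfg.n_samples]
    cluster = rng.permutation(base)

    signatures = _cluster_signatures(cfg.n_clusters, cfg.n_topics)
    phi = _topic_gene_distributions(cfg, rng)

    theta = np.zeros((cfg.n_samples, cfg.n_topics))
    for s in range(cfg.n_samples):
        sig = signatures[cluster[s]]
        if cfg.mixture_concentration == 0:
            theta[s, rng.choice(cfg.n_topics, p=sig)] = 1.0
        else:
            theta[s] = rng.dirichlet(cfg.mixture_concentration * sig)

    sample_probs = theta @ phi  # sample x gene
    depths = rng.poisson(cfg.depth_mean, size=cfg.n_samples)
    counts = np.zeros((cfg.n_genes, cfg.n_samples))
    for s in range(cfg.n_samples):
        counts[:, s] = rng.multinomial(depths[s], sample_probs[s])

    expr = ExpressionMatrix(counts,
                            [f"g{i}" for i in range(cfg.n_genes)],
                            [f"s{j}" for j in range(cfg.n_samples)])
    subtype = np.array([f"subtype{k}" for k in cluster])
    truth = SyntheticTruth(theta=theta, phi=phi, cluster_label=cluster,
                           subtype_label=subtype)
    return expr, truth


def generate_survival(truth: SyntheticTruth, config: SyntheticConfig,
                      driver_topic: int = 0) -> pd.DataFrame:
    """Exponential survival times whose hazard depends on one topic.

    Samples with driver-topic weight above the cohort median have hazard
    ``baseline_hazard * topic_hazard_ratio``; others ``baseline_hazard``.
    Independent uniform censoring is scaled so that the realized censored
    fraction approximates ``censoring_fraction``.  Returns a clinical
    table with columns sample_id, subtype, duration_days, event.
    """
    cfg = config
    if cfg.baseline_hazard <= 0 or cfg.topic_hazard_ratio <= 0:
        raise ValueError("hazard parameters must be positive")
    if not 0 <= driver_topic < truth.theta.shape[1]:
        raise ValueError("driver_topic out of range")
    rng = np.random.default_rng(cfg.seed + 1)

    weight = truth.theta[:, driver_topic]
    high = weight > np.median(weight)
    hazard = cfg.baseline_hazard * np.where(high, cfg.topic_hazard_ratio, 1.0)
    times = rng.exponential(1.0 / hazard)

    if cfg.censoring_fraction == 0:
        duration, event = times, np.ones(times.size, dtype=int)
    else:
        u = rng.uniform(size=times.size)
        # scale uniform censoring times to hit the requested fraction
        lo, hi = 1e-9, times.max() * 10
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = np.mean(times > mid * u)
            if frac > cfg.censoring_fraction:
                lo = mid
            else:
                hi = mid
        cmax = 0.5 * (lo + hi)
        censor = cmax * u
        event = (times <= censor).astype(int)
        duration = np.minimum(times, censor)

    table = pd.DataFrame({
        "sample_id": truth.sample_ids,
        "subtype": truth.subtype_label,
        "duration_days": np.maximum(duration, 1e-9),
        "event": event,
    })
    truth.survival = table
    return table


def generate_stage_labels(truth: SyntheticTruth, config: SyntheticConfig,
                          driver_topic: int = 0) -> np.ndarray:
    """Assign tumor stages i-iv correlated with the driver topic.

    In the first subtype the expected driver-topic weight increases with
    stage (slope ``stage_trend_slope`` per step); in the second it
    decreases.  Requires at least two subtypes.
    """
    cfg = config
    subtypes = sorted(set(truth.subtype_label))
    if len(subtypes) < 2:
        raise ValueError("stage trends require at least two subtypes")
    if not 0 <= driver_topic < truth.theta.shape[1]:
        raise ValueError("driver_topic out of range")
    rng = np.random.default_rng(cfg.seed + 2)

    weight = truth.theta[:, driver_topic]
    sd = weight.std() or 1.0
    z = (weight - weight.mean()) / sd
    sign = np.where(truth.subtype_label == subtypes[0], 1.0, -1.0)
    score = cfg.stage_trend_slope * sign * z + rng.standard_normal(weight.size)

    stages = np.empty(weight.size, dtype=object)
    for sub in subtypes:
        mask = truth.subtype_label == sub
        # quartile-bin the score within each subtype -> stages i..iv
        qs = np.quantile(score[mask], [0.25, 0.5, 0.75])
        stages[mask] = np.array(STAGES)[np.searchsorted(qs, score[mask])]
    truth.stage_label = stages.astype(str)
    return truth.stage_label


def generate_dataset(config: SyntheticConfig, driver_topic: int = 0
                     ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Full synthetic dataset: expression, stages and survival in one call."""
    expr, truth = generate_expression(config)
    if len(set(truth.subtype_label)) >= 2:
        generate_stage_labels(truth, config, driver_topic)
    clin = generate_survival(truth, config, driver_topic)
    if truth.stage_label is not None:
        clin["stage"] = truth.stage_label
    return expr, truth


def write_truth(truth: SyntheticTruth, directory) -> None:
    """Serialize the planted truth as plain-text tables."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.theta, index=truth.sample_ids).to_csv(
        d / "theta.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(truth.phi,
                 columns=[f"g{i}" for i in range(truth.phi.shape[1])]).to_csv(
        d / "phi.tsv", sep="\t", index_label="topic")
    labels = pd.DataFrame({
        "sample_id": truth.sample_ids,
        "cluster": truth.cluster_label,
        "subtype": truth.subtype_label,
    })
    if truth.stage_label is not None:
        labels["stage"] = truth.stage_label
    labels.to_csv(d / "labels.tsv", sep="\t", index=False)
    if truth.survival is not None:
        truth.survival.to_csv(d / "clinical.tsv", sep="\t", index=False)


def read_truth(directory) -> SyntheticTruth:
    import pathlib

    d = pathlib.Path(directory)
    theta = pd.read_csv(d / "theta.tsv", sep="\t", index_col=0).to_numpy()
    phi = pd.read_csv(d / "phi.tsv", sep="\t", index_col=0).to_numpy()
    labels = pd.read_csv(d / "labels.tsv", sep="\t")
    truth = SyntheticTruth(
        theta=theta, phi=phi,
        cluster_label=labels["cluster"].to_numpy(),
        subtype_label=labels["subtype"].to_numpy().astype(str),
        stage_label=labels["stage"].to_numpy().astype(str) if "stage" in labels else None,
    )
    clin_path = d / "clinical.tsv"
    if clin_path.exists():
        truth.survival = pd.read_csv(clin_path, sep="\t")
    return truth
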