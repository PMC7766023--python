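# topicsbm

Topic modeling of cancer transcriptomes with a bipartite stochastic
block model.

Bulk RNA-seq cohorts such as the TCGA breast (BRCA) and non-small-cell
lung (LUAD/LUSC) collections mix strong, overlapping expression programs:
subtype signatures, proliferation, stromal and immune content.  Viewing
the gene × sample expression matrix as a weighted bipartite multigraph —
each unit of expression one edge between a gene and a sample — turns
topic modeling into community detection: **topics** are blocks of genes,
**clusters** are blocks of samples, and both are inferred *jointly and
non-parametrically* by minimizing a description length

$$\Sigma = -\sum_{r,c} e_{rc}\ln\frac{e_{rc}E}{e_r e_c}
\;+\; C_{\text{model}}(b) \qquad [\text{nats}],$$

a degree-corrected block entropy plus flat counting costs for the
partitions, the block edge-count matrix and the degree sequences.  From
the fitted blocks, half-edge counting gives P(topic|sample) — each
sample's topic mixture — and P(gene|topic) — each topic's gene ranking.
The package then carries these objects through the downstream analyses
of a cancer-transcriptome study:

- **cluster/label agreement** via NMI normalized by a fixed-cluster-size
  label-reshuffling null (NMI/NMI\*);
- **topic enrichment** across subtypes and tumor stages (centered
  mixtures, group aggregation, ranked gene-list export);
- **survival**: lifetime construction from vital-status fields, stage
  cleaning, a binary topic up-regulation feature (weight above the
  cohort median), Cox proportional-hazards fits, and per-cluster
  five-year survival z-scores against a record-reshuffling null;
- **classification** of subtypes in topic space with a one-hidden-layer
  network (SGD, cross-entropy) and a k-NN baseline;
- a **synthetic-data generator** with planted topic/cluster structure
  and matching clinical metadata, so every stage is testable without
  external downloads.

It is aimed at computational biologists who want a transparent,
reproducible, pure-Python counterpart to graph-tool-based topic-model
pipelines, with every modeling choice documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Fit a small planted dataset end to end:

```python
import pandas as pd
from topicsbm import SyntheticConfig, TopicBlockModel
from topicsbm.synthetic import generate_dataset

cfg = SyntheticConfig(n_samples=60, n_genes=120, n_clusters=2, n_topics=3,
                      depth_mean=400.0, seed=11)
expr, truth = generate_dataset(cfg)

model = TopicBlockModel(expr.to_frame(), discretize="exact")
results = model.fit(n_restarts=3, seed=0)
print(results.summary())
```

```
Bipartite topic block model
==========================================================
genes: 120   samples: 60   edge mass E: 23562
restarts: 3   seed: 0
----------------------------------------------------------
level   topics  clusters     sigma (nats)
    0        3         6          -892.68
    1        2         2          -473.62
    2        1         1          1163.70
```

Level 0 is the finest description-length optimum (here 3 topics, 6
sample blocks — sub-structure within the two planted clusters); higher
levels are coarser resolutions, ending at one block per side.  Scoring
the clusters against the planted labels at every level:

```python
labels = pd.Series(truth.cluster_label, index=expr.samples)
print(results.score_against(labels, reps=100, seed=0).round(3))
```

```
 level  n_clusters   nmi  nmi_star  normalized
     0           6 0.566     0.035      16.255
     1           2 1.000     0.012      86.901
     2           1 0.000     0.000       1.000
```

At level 1 the two planted clusters are recovered exactly (NMI = 1);
the normalized column divides by the reshuffling null NMI\*, so values
far above 1 mean far-better-than-chance agreement, and the trivial
single-cluster level maps to 1 by convention.  Scanning topics for a
survival association with the built-in clinical table:

```python
for t in range(3):
    cox = results.survival_analysis(truth.survival, topic=t)
    print(f"topic{t}: HR={cox.hazard_ratio:.3f}  p={cox.p_value:.3g}")
```

```
topic0: HR=1.120  p=0.697
topic1: HR=2.998  p=0.000485
topic2: HR=0.334  p=0.000485
```

Topic 1 is the planted driver: samples with its weight above the cohort
median have about three times the death hazard in this small cohort
(planted ratio 2; n = 60).  Topic 2's hazard ratio is its mirror image —
mixture weights are compositional, so depletion of one topic is
enrichment of another.

The same workflow is available from the shell:

```bash
topicsbm simulate --preset tiny --seed 3 --out data/
topicsbm fit --graph edges.tsv --restarts 10 --seed 0 --out fit/run
topicsbm score --clusters clusters.tsv --labels labels.tsv --reps 100 --seed 0
```

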