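"""Bipartite degree-corrected stochastic block model inferred by MDL.

Genes and samples are partitioned simultaneously into blocks (topics and
clusters) by minimizing a description length

    sigma = likelihood term + model cost        [nats]

The likelihood term is the degree-corrected multigraph block entropy in
its normalized (mutual-information) form,

    L = - sum_{r,c} e_rc * ln( e_rc * E / (e_r * e_c) ),

summed over gene-block/sample-block pairs, where e_rc is the edge mass
between blocks, e_r / e_c are block half-edge totals and E the total edge
mass (0 ln 0 := 0).  L is 0 when each side forms a single block and
decreases (improves) as the partition captures structure.  The model cost
charges flat Dirichlet-multinomial counting prices for the number of
blocks, the block sizes, the assignment, the block edge-count matrix and
the within-block degree sequences, so that finer partitions must pay for
their extra parameters.

Inference is agglomerative/greedy: seeded random restarts, single-node
move sweeps with a brief simulated-annealing phase, and pairwise block
merges, never moving a node across the bipartition.  A hierarchy is built
by recursively block-modeling the block multigraph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .bigraph import BipartiteGraph

_EPS = 1e-10


# --------------------------------------------------------------------------
# description length
# --------------------------------------------------------------------------

def _xlogx(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _ln_binom(a, b):
    """ln C(a, b) via gammaln; vectorized."""
    return gammaln(np.asarray(a, float) + 1) - gammaln(np.asarray(b, float) + 1) \
        - gammaln(np.asarray(a, float) - np.asarray(b, float) + 1)


def _degree_cost(e, n):
    """Cost of a degree sequence summing to e over n nodes: ln C(e+n-1, n-1)."""
    e = np.asarray(e, float)
    n = np.asarray(n, float)
    safe_n = np.maximum(n, 1.0)  # avoid gammaln(0) in the unused branch
    return np.where(n > 0, _ln_binom(e + safe_n - 1, safe_n - 1), 0.0)


def _partition_cost(sizes: np.ndarray, n_total: int) -> float:
    """Flat prior cost of a labeled partition with the given block sizes."""
    b = sizes.size
    return (np.log(n_total)
            + _ln_binom(n_total - 1, b - 1)
            + gammaln(n_total + 1) - gammaln(sizes + 1.0).sum())


def _as_side_arrays(graph: BipartiteGraph, assignment):
    """Accept (gene_blocks, sample_blocks) arrays or a node->block mapping."""
    if isinstance(assignment, dict):
        gene_blocks = np.array([assignment[g] for g in graph.genes])
        sample_blocks = np.array([assignment[s] for s in graph.samples])
        if set(gene_blocks.tolist()) & set(sample_blocks.tolist()):
            raise ValueError("a block may not contain both genes and samples")
        return _dense(gene_blocks), _dense(sample_blocks)
    gene_blocks, sample_blocks = assignment
    return (np.asarray(gene_blocks, dtype=np.int64),
            np.asarray(sample_blocks, dtype=np.int64))


def _dense(labels: np.ndarray) -> np.ndarray:
    """Relabel to dense consecutive ids in first-occurrence order."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[x] for x in labels], dtype=np.int64)


def _block_matrix(graph: BipartiteGraph, gene_blocks, sample_blocks):
    bg = int(gene_blocks.max()) + 1 if gene_blocks.size else 0
    bs = int(sample_blocks.max()) + 1 if sample_blocks.size else 0
    e = np.zeros((bg, bs))
    np.add.at(e, (gene_blocks[graph.gene_idx], sample_blocks[graph.sample_idx]),
              graph.mult)
    return e


def description_length(graph: BipartiteGraph, assignment) -> float:
    """Description length sigma (nats) of an assignment; pure and exact.

    ``assignment`` is either a pair of per-side label arrays
    (gene_blocks, sample_blocks) or a mapping node-id -> block; a block
    mixing the two sides raises.
    """
    gene_blocks, sample_blocks = _as_side_arrays(graph, assignment)
    if gene_blocks.size != graph.n_genes or sample_blocks.size != graph.n_samples:
        raise ValueError("assignment length does not match the graph")
    gene_blocks, sample_blocks = _dense(gene_blocks), _dense(sample_blocks)

    e = _block_matrix(graph, gene_blocks, sample_blocks)
    e_g, e_s = e.sum(axis=1), e.sum(axis=0)
    total = graph.total_edges
    likelihood = float(_xlogx(e_g).sum() + _xlogx(e_s).sum()
                       - _xlogx(e).sum() - _xlogx([total]).sum())

    sizes_g = np.bincount(gene_blocks).astype(float)
    sizes_s = np.bincount(sample_blocks).astype(float)
    cost = (_partition_cost(sizes_g, graph.n_genes)
            + _partition_cost(sizes_s, graph.n_samples)
            + float(_ln_binom(total + e.size - 1, e.size - 1))
            + float(_degree_cost(e_g, sizes_g).sum())
            + float(_degree_cost(e_s, sizes_s).sum()))
    return likelihood + cost


# --------------------------------------------------------------------------
# exhaustive oracle
# --------------------------------------------------------------------------

def _set_partitions(n: int):
    """All set partitions of range(n) as dense label arrays (rgs order)."""
    from sympy.utilities.iterables import multiset_partitions

    if n == 0:
        yield np.zeros(0, dtype=np.int64)
        return
    if n == 1:
        yield np.zeros(1, dtype=np.int64)
        return
    for parts in multiset_partitions(list(range(n))):
        labels = np.empty(n, dtype=np.int64)
        for b, members in enumerate(parts):
            labels[list(members)] = b
        yield _dense(labels)


def exhaustive_minimize(graph: BipartiteGraph) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Global MDL minimum by enumerating every bipartition-respecting assignment.

    Testing oracle; refuses graphs with more than 10 nodes.  Ties are
    broken toward the lexicographically smallest canonical label pair.
    """
    if graph.n_genes + graph.n_samples > 10:
        raise ValueError("exhaustive enumeration is limited to <= 10 nodes")
    best = None
    best_sigma = np.inf
    best_key = None
    sample_parts = list(_set_partitions(graph.n_samples))
    for gp in _set_partitions(graph.n_genes):
        for sp in sample_parts:
            sigma = description_length(graph, (gp, sp))
            key = (tuple(gp), tuple(sp))
            if sigma < best_sigma - _EPS or (
                    abs(sigma - best_sigma) <= _EPS and key < best_key):
                best, best_sigma, best_key = (gp.copy(), sp.copy()), sigma, key
    return best, best_sigma


# --------------------------------------------------------------------------
# greedy fit
# --------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit`."""

    n_restarts: int = 10
    seed: int = 0
    max_sweeps: int = 100
    objective_variant: str = "dcsbm_flat"
    anneal_t0: float = 3.0
    anneal_decay: float = 0.6
    anneal_sweeps: int = 4
    # start from many blocks and let sweeps + merges coarsen: greedy SBM
    # optimization is far more reliable top-down than bottom-up
    init_blocks: tuple[int, ...] = (25, 13, 40, 8, 20, 5, 2)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.objective_variant != "dcsbm_flat":
            raise ValueError(f"unknown objective variant {self.objective_variant!r}")


class _State:
    """Incrementally maintained partition state for one restart."""

    def __init__(self, graph: BipartiteGraph, gene_blocks, sample_blocks):
        self.graph = graph
        self.labels = [np.asarray(gene_blocks, dtype=np.int64).copy(),
                       np.asarray(sample_blocks, dtype=np.int64).copy()]
        self.n_nodes = [graph.n_genes, graph.n_samples]
        self.total = float(graph.total_edges)
        # adjacency: per node on each side, neighbor indices + multiplicities
        self.nbrs = [self._adj(graph.gene_idx, graph.sample_idx, graph.mult,
                               graph.n_genes),
                     self._adj(graph.sample_idx, graph.gene_idx, graph.mult,
                               graph.n_samples)]
        self._rebuild()

    @staticmethod
    def _adj(own_idx, other_idx, mult, n_own):
        order = np.argsort(own_idx, kind="stable")
        own_sorted = own_idx[order]
        bounds = np.searchsorted(own_sorted, np.arange(n_own + 1))
        oi, mm = other_idx[order], mult[order]
        return [(oi[bounds[v]:bounds[v + 1]], mm[bounds[v]:bounds[v + 1]])
                for v in range(n_own)]

    def _rebuild(self) -> None:
        self.labels = [_dense(self.labels[0]), _dense(self.labels[1])]
        bg = int(self.labels[0].max()) + 1
        bs = int(self.labels[1].max()) + 1
        e = np.zeros((bg, bs))
        g = self.graph
        np.add.at(e, (self.labels[0][g.gene_idx], self.labels[1][g.sample_idx]),
                  g.mult)
        self.e = e
        self.tots = [e.sum(axis=1), e.sum(axis=0)]
        self.sizes = [np.bincount(self.labels[0], minlength=bg).astype(float),
                      np.bincount(self.labels[1], minlength=bs).astype(float)]

    def n_blocks(self, side: int) -> int:
        return int((self.sizes[side] > 0).sum())

    def sigma(self) -> float:
        return description_length(self.graph, (self.labels[0], self.labels[1]))

    # -- single node moves -------------------------------------------------
    def _matrix(self, side: int) -> np.ndarray:
        """e viewed with the given side's blocks as rows."""
        return self.e if side == 0 else self.e.T

    def try_move(self, side: int, v: int, rng, temperature: float) -> bool:
        labels = self.labels[side]
        sizes = self.sizes[side]
        tots = self.tots[side]
        m = self._matrix(side)
        a = labels[v]
        n_slots = sizes.size
        nbr_idx, nbr_w = self.nbrs[side][v]
        d = np.bincount(self.labels[1 - side][nbr_idx], weights=nbr_w,
                        minlength=self.e.shape[1 - side])
        touched = np.flatnonzero(d)
        dt = d[touched]
        k = dt.sum()

        b_own = self.n_blocks(side)
        b_other = self.n_blocks(1 - side)
        n_tot = self.n_nodes[side]

        # allow opening one fresh block
        empty_slots = np.flatnonzero(sizes == 0)
        new_slot = -1
        if b_own < n_tot:
            if empty_slots.size:
                new_slot = int(empty_slots[0])
            else:
                self._grow(side)
                sizes = self.sizes[side]
                tots = self.tots[side]
                m = self._matrix(side)
                n_slots = sizes.size
                new_slot = n_slots - 1

        # removal from a (independent of target)
        row_a = m[a, touched]
        d_l_rm = (_xlogx(tots[a] - k) - _xlogx(tots[a])
                  - (_xlogx(row_a - dt) - _xlogx(row_a)).sum())
        d_c_rm = (_degree_cost(tots[a] - k, sizes[a] - 1)
                  - _degree_cost(tots[a], sizes[a])
                  + gammaln(sizes[a] + 1) - gammaln(sizes[a]))

        # addition to every slot, vectorized
        rows = m[:, touched]
        d_l_add = (_xlogx(tots + k) - _xlogx(tots)
                   - (_xlogx(rows + dt[None, :]) - _xlogx(rows)).sum(axis=1))
        d_c_add = (_degree_cost(tots + k, sizes + 1) - _degree_cost(tots, sizes)
                   - (gammaln(sizes + 2) - gammaln(sizes + 1)))

        delta = d_l_rm + d_c_rm + d_l_add + d_c_add

        # number-of-blocks terms
        a_empties = sizes[a] == 1
        is_new = sizes == 0
        b_after = b_own - int(a_empties) + is_new.astype(int)
        change = b_after != b_own
        if np.any(change) or a_empties:
            base = (_ln_binom(n_tot - 1, b_own - 1)
                    + _ln_binom(self.total + b_own * b_other - 1,
                                b_own * b_other - 1))
            after = (_ln_binom(n_tot - 1, b_after - 1)
                     + _ln_binom(self.total + b_after * b_other - 1,
                                 b_after * b_other - 1))
            delta = delta + (after - base)

        mask = np.ones(n_slots, dtype=bool)
        mask[a] = False
        mask[is_new] = False
        if new_slot >= 0:
            mask[new_slot] = True
        if not mask.any():
            return False
        cand = np.flatnonzero(mask)
        best = cand[np.argmin(delta[cand])]
        dbest = delta[best]
        accept = dbest < -_EPS
        if not accept and temperature > 0 and np.isfinite(dbest):
            accept = rng.random() < np.exp(-max(dbest, 0.0) / temperature)
        if not accept:
            return False

        # apply
        m[a, touched] -= dt
        m[best, touched] += dt
        tots[a] -= k
        tots[best] += k
        sizes[a] -= 1
        sizes[best] += 1
        self.labels[side][v] = best
        return True

    def _grow(self, side: int) -> None:
        if side == 0:
            self.e = np.vstack([self.e, np.zeros((1, self.e.shape[1]))])
        else:
            self.e = np.hstack([self.e, np.zeros((self.e.shape[0], 1))])
        self.tots[side] = np.append(self.tots[side], 0.0)
        self.sizes[side] = np.append(self.sizes[side], 0.0)

    # -- merges ------------------------------------------------------------
    def best_merge(self, side: int):
        sizes = self.sizes[side]
        tots = self.tots[side]
        m = self._matrix(side)
        blocks = np.flatnonzero(sizes > 0)
        b_own = blocks.size
        if b_own < 2:
            return None
        b_other = self.n_blocks(1 - side)
        n_tot = self.n_nodes[side]
        b_term = (_ln_binom(n_tot - 1, b_own - 2) - _ln_binom(n_tot - 1, b_own - 1)
                  + _ln_binom(self.total + (b_own - 1) * b_other - 1,
                              (b_own - 1) * b_other - 1)
                  - _ln_binom(self.total + b_own * b_other - 1,
                              b_own * b_other - 1))
        best = None
        for i in range(b_own):
            r1 = blocks[i]
            for j in range(i + 1, b_own):
                r2 = blocks[j]
                merged = m[r1] + m[r2]
                d_l = (_xlogx(tots[r1] + tots[r2]) - _xlogx(tots[r1])
                       - _xlogx(tots[r2])
                       - (_xlogx(merged) - _xlogx(m[r1]) - _xlogx(m[r2])).sum())
                d_c = (_degree_cost(tots[r1] + tots[r2], sizes[r1] + sizes[r2])
                       - _degree_cost(tots[r1], sizes[r1])
                       - _degree_cost(tots[r2], sizes[r2])
                       - gammaln(sizes[r1] + sizes[r2] + 1)
                       + gammaln(sizes[r1] + 1) + gammaln(sizes[r2] + 1))
                delta = float(d_l + d_c + b_term)
                if best is None or delta < best[0]:
                    best = (delta, r1, r2)
        return best

    def apply_merge(self, side: int, r1: int, r2: int) -> None:
        self.labels[side][self.labels[side] == r2] = r1
        self._rebuild()


def _greedy_phase(state: _State, cfg: FitConfig, rng) -> None:
    schedule = [cfg.anneal_t0 * cfg.anneal_decay ** t
                for t in range(cfg.anneal_sweeps)] + [0.0]
    nodes = [(side, v) for side in (0, 1) for v in range(state.n_nodes[side])]
    sweeps = 0
    t_idx = 0
    while sweeps < cfg.max_sweeps:
        temperature = schedule[min(t_idx, len(schedule) - 1)]
        order = rng.permutation(len(nodes))
        moved = 0
        for pos in order:
            side, v = nodes[pos]
            if state.try_move(side, v, rng, temperature):
                moved += 1
        sweeps += 1
        t_idx += 1
        if moved == 0 and temperature == 0.0:
            break
    state._rebuild()


def _merge_phase(state: _State) -> bool:
    any_merge = False
    improved = True
    while improved:
        improved = False
        for side in (0, 1):
            best = state.best_merge(side)
            if best is not None and best[0] < -_EPS:
                state.apply_merge(side, best[1], best[2])
                improved = True
                any_merge = True
    return any_merge


def _fit_flat(graph: BipartiteGraph, cfg: FitConfig
              ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Single-level fit: best assignment over seeded restarts."""
    if graph.total_edges == 0:
        raise ValueError("cannot fit an edgeless graph")
    best = None
    best_sigma = np.inf
    best_key = None
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng((cfg.seed, r))
        b0 = cfg.init_blocks[r % len(cfg.init_blocks)]
        state = _State(graph,
                       rng.integers(0, max(1, min(b0, graph.n_genes)),
                                    graph.n_genes),
                       rng.integers(0, max(1, min(b0, graph.n_samples)),
                                    graph.n_samples))
        for _ in range(10):  # alternate sweeps and merges until stable
            _greedy_phase(state, cfg, rng)
            if not _merge_phase(state):
                break
        labels = (_dense(state.labels[0]), _dense(state.labels[1]))
        sigma = description_length(graph, labels)
        key = (tuple(labels[0]), tuple(labels[1]))
        if sigma < best_sigma - _EPS or (
                abs(sigma - best_sigma) <= _EPS and (best_key is None or key < best_key)):
            best, best_sigma, best_key = labels, sigma, key

    # contract: never worse than the trivial baselines
    one = (np.zeros(graph.n_genes, dtype=np.int64),
           np.zeros(graph.n_samples, dtype=np.int64))
    singles = (np.arange(graph.n_genes), np.arange(graph.n_samples))
    for cand in (one, singles):
        sigma = description_length(graph, cand)
        if sigma < best_sigma - _EPS:
            best, best_sigma = cand, sigma
    return best, best_sigma


# --------------------------------------------------------------------------
# hierarchy
# --------------------------------------------------------------------------

@dataclass
class Level:
    """One hierarchy level: per-node block ids and its description length."""

    gene_blocks: np.ndarray
    sample_blocks: np.ndarray
    sigma: float

    @property
    def n_topics(self) -> int:
        return int(self.gene_blocks.max()) + 1

    @property
    def n_clusters(self) -> int:
        return int(self.sample_blocks.max()) + 1


@dataclass
class BlockHierarchy:
    """Nested bipartite partitions, level 0 finest; coarsenings above."""

    genes: list[str]
    samples: list[str]
    levels: list[Level] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, idx: int) -> Level:
        if not 0 <= idx < len(self.levels):
            raise ValueError(f"no hierarchy level {idx}")
        return self.levels[idx]

    # ------------------------------------------------------------------ I/O
    def write(self, assignments_path, meta_path=None) -> None:
        import pandas as pd

        rows = []
        for lvl, level in enumerate(self.levels):
            for g, b in zip(self.genes, level.gene_blocks):
                rows.append((g, "gene", lvl, int(b)))
            for s, b in zip(self.samples, level.sample_blocks):
                rows.append((s, "sample", lvl, int(b)))
        pd.DataFrame(rows, columns=["node_id", "side", "level", "block_id"]
                     ).to_csv(assignments_path, sep="\t", index=False)
        if meta_path is not None:
            meta = [{"level": lvl, "sigma": level.sigma,
                     "n_topics": level.n_topics, "n_clusters": level.n_clusters}
                    for lvl, level in enumerate(self.levels)]
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, assignments_path, graph: BipartiteGraph | None = None,
             meta_path=None) -> "BlockHierarchy":
        import pandas as pd

        df = pd.read_csv(assignments_path, sep="\t")
        genes = df[df.side == "gene"].node_id.unique().tolist()
        samples = df[df.side == "sample"].node_id.unique().tolist()
        gpos = {g: i for i, g in enumerate(genes)}
        spos = {s: j for j, s in enumerate(samples)}
        h = cls(genes, samples)
        sigmas = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                sigmas = {m["level"]: m["sigma"] for m in json.load(fh)}
        for lvl in sorted(df.level.unique()):
            sub = df[df.level == lvl]
            gb = np.zeros(len(genes), dtype=np.int64)
            sb = np.zeros(len(samples), dtype=np.int64)
            for _, row in sub.iterrows():
                if row.side == "gene":
                    gb[gpos[row.node_id]] = row.block_id
                else:
                    sb[spos[row.node_id]] = row.block_id
            sigma = sigmas.get(lvl, np.nan)
            if np.isnan(sigma) and graph is not None:
                sigma = description_length(graph, (gb, sb))
            h.levels.append(Level(gb, sb, float(sigma)))
        return h


def _merge_loss(e: np.ndarray, tots: np.ndarray, axis: int) -> np.ndarray:
    """Likelihood-term loss for merging every block pair along one axis.

    Merging blocks with proportional connectivity profiles loses zero
    mutual information; dissimilar profiles pay in proportion to the
    information their distinction carries.  Returns a (B, B) matrix with
    +inf on and below the diagonal.
    """
    m = e if axis == 0 else e.T
    b = m.shape[0]
    loss = np.full((b, b), np.inf)
    for i in range(b):
        for j in range(i + 1, b):
            merged_rows = m[i] + m[j]
            loss[i, j] = (_xlogx(tots[i] + tots[j]) - _xlogx(tots[i])
                          - _xlogx(tots[j])
                          - (_xlogx(merged_rows) - _xlogx(m[i])
                             - _xlogx(m[j])).sum())
    return loss


def _merge_cascade(e0: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Coarsen a block edge-count matrix into levels of resolution.

    Starting from the finest block matrix, repeatedly merges the pair of
    blocks (on either side) whose merge loses the least likelihood; a
    level is emitted each time the total block count halves, ending at
    one block per side.  Deterministic; returns super-partitions of the
    finest blocks, finest to coarsest.
    """
    part_g = np.arange(e0.shape[0])
    part_s = np.arange(e0.shape[1])
    e = e0.astype(float).copy()
    levels: list[tuple[np.ndarray, np.ndarray]] = []
    next_emit = (e.shape[0] + e.shape[1]) // 2
    while e.shape[0] + e.shape[1] > 2:
        tots_g, tots_s = e.sum(axis=1), e.sum(axis=0)
        candidates = []
        if e.shape[0] > 1:
            loss_g = _merge_loss(e, tots_g, axis=0)
            i, j = np.unravel_index(np.argmin(loss_g), loss_g.shape)
            candidates.append((loss_g[i, j], 0, i, j))
        if e.shape[1] > 1:
            loss_s = _merge_loss(e, tots_s, axis=1)
            i, j = np.unravel_index(np.argmin(loss_s), loss_s.shape)
            candidates.append((loss_s[i, j], 1, i, j))
        _, side, i, j = min(candidates, key=lambda c: (c[0], c[1]))
        if side == 0:
            e[i] += e[j]
            e = np.delete(e, j, axis=0)
            part_g[part_g == j] = i
            part_g[part_g > j] -= 1
        else:
            e[:, i] += e[:, j]
            e = np.delete(e, j, axis=1)
            part_s[part_s == j] = i
            part_s[part_s > j] -= 1
        if e.shape[0] + e.shape[1] <= max(next_emit, 2):
            levels.append((part_g.copy(), part_s.copy()))
            next_emit = (e.shape[0] + e.shape[1]) // 2
    if not levels or levels[-1][0].max() + levels[-1][1].max() > 0:
        levels.append((np.zeros_like(part_g), np.zeros_like(part_s)))
    return levels


def fit(graph: BipartiteGraph, config: FitConfig | None = None) -> BlockHierarchy:
    """Infer the block hierarchy of a bipartite multigraph.

    Level 0 is the finest MDL partition found by the restart/sweep/merge
    optimizer; higher levels of resolution come from an agglomerative
    cascade on the block multigraph, merging at each step the block pair
    whose fusion loses the least likelihood and recording a level each
    time the block count halves, down to one block per side.  The sigma
    reported for every level is the flat description length of that
    level's assignment on the original graph; level 0's sigma is never
    worse than either trivial baseline.
    """
    cfg = config or FitConfig()
    labels, sigma = _fit_flat(graph, cfg)
    hierarchy = BlockHierarchy(list(graph.genes), list(graph.samples))
    hierarchy.levels.append(Level(labels[0], labels[1], sigma))

    base = hierarchy.levels[0]
    if base.n_topics > 1 or base.n_clusters > 1:
        e0 = _block_matrix(graph, base.gene_blocks, base.sample_blocks)
        for part_g, part_s in _merge_cascade(e0):
            gb = _dense(part_g[base.gene_blocks])
            sb = _dense(part_s[base.sample_blocks])
            hierarchy.levels.append(
                Level(gb, sb, description_length(graph, (gb, sb))))
    return hierarchy


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

def extract_clusters(hierarchy: BlockHierarchy, level: int = 0) -> dict[str, int]:
    """Sample -> cluster map at a level, ids dense and consecutive."""
    lv = hierarchy.level(level)
    dense = _dense(lv.sample_blocks)
    return dict(zip(hierarchy.samples, dense.tolist()))


def extract_topics(hierarchy: BlockHierarchy, level: int = 0) -> dict[str, int]:
    """Gene -> topic map at a level, ids dense and consecutive."""
    lv = hierarchy.level(level)
    dense = _dense(lv.gene_blocks)
    return dict(zip(hierarchy.genes, dense.tolist()))
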