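"""Simulators: mixture alignments, random SPR neighbors, and a 4-taxon
coalescent with a single introgression pulse.

These generators define the study conditions for the recovery and
model-selection experiments: alignments are evolved site by site down each
class tree (root states from the stationary frequencies, one uniformly
drawn gamma category per site), class membership is either drawn iid from
the mixture weights or laid out in contiguous blocks, and misspecified
input topologies are produced by sequential random subtree prune-regraft
moves.  The coalescent sampler is a purpose-built 4-population structured
coalescent: one lineage per species, stepwise population mergers at the
species-tree divergence times, and a pulse migration of the recipient
lineage into the donor population with probability ``r`` at the
introgression time (all times in coalescent units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .likelihood import ClassModel
from .models import build_rate_matrix
from .trees import TreeTopology, TreeError


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# sequence simulation

_STATE_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)


def simulate_alignment(cm: ClassModel, n_sites: int, seed) -> Alignment:
    """Evolve ``n_sites`` iid sites down ``cm.tree`` under GTR+G.

    Root states are drawn from the stationary frequencies; each site gets
    one gamma category, constant across the whole tree (the discrete +G
    assumption).  Reproducible given the seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    tree = cm.tree
    Q = build_rate_matrix(cm.gtr, cm.freqs)
    rates = cm.rhas.category_rates
    ncat = cm.rhas.ncat

    cat = rng.integers(ncat, size=n_sites)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=n_sites, p=cm.freqs.pi)
    order = list(reversed(tree.postorder()))  # preorder
    for v in order:
        if v == tree.root:
            continue
        P = Q.transition_batch(np.asarray(rates) * float(tree.lengths[v]))  # (ncat,4,4)
        rows = P[cat, states[tree.parent[v]]]        # (n_sites, 4)
        cum = np.cumsum(rows, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n_sites)
        states[v] = (u[:, None] > cum).sum(axis=1)
    data = _STATE_BITS[states[: tree.n_tips]]
    return Alignment(taxon_labels=list(tree.tip_labels), data=data)


@dataclass
class MixtureSimSpec:
    """Mixture-alignment simulation: one ClassModel per class, with class
    membership either iid from ``weights`` or in contiguous blocks of
    ``block_lengths`` (block lengths must sum to ``n_sites``)."""

    classes: list[ClassModel]
    n_sites: int
    weights: np.ndarray | None = None
    block_lengths: list[int] | None = None
    mode: str = "iid"
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("iid", "block"):
            raise ValueError("mode must be 'iid' or 'block'")
        if self.mode == "iid":
            if self.weights is None:
                raise ValueError("iid mode needs weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.classes):
                raise ValueError("one weight per class required")
            if abs(self.weights.sum() - 1.0) > 1e-8:
                raise ValueError("weights must sum to 1")
        else:
            if self.block_lengths is None:
                raise ValueError("block mode needs block_lengths")
            if len(self.block_lengths) != len(self.classes):
                raise ValueError("one block length per class required")
            if sum(self.block_lengths) != self.n_sites:
                raise ValueError("block lengths must sum to n_sites")


def simulate_mixture(spec: MixtureSimSpec):
    """Returns ``(Alignment, labels)`` where ``labels[i]`` is the 0-based
    class index each site was simulated under."""
    rng = _rng(spec.seed)
    m = len(spec.classes)
    if spec.mode == "block":
        labels = np.repeat(np.arange(m), spec.block_lengths)
    else:
        labels = rng.choice(m, size=spec.n_sites, p=spec.weights)
    data = np.empty((len(spec.classes[0].tree.tip_labels), spec.n_sites),
                    dtype=np.uint8)
    taxa = spec.classes[0].tree.tip_labels
    for j, cm in enumerate(spec.classes):
        if cm.tree.tip_labels != taxa:
            raise ValueError("all classes must share one tip set")
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            continue
        sub = simulate_alignment(cm, idx.size, rng)
        data[:, idx] = sub.data
    return Alignment(taxon_labels=list(taxa), data=data), labels


# ---------------------------------------------------------------------------
# SPR moves


def spr_move(tree: TreeTopology, rng) -> TreeTopology:
    """One uniform-random subtree prune-regraft that changes the unrooted
    topology.  The pruned edge keeps its length; the regraft edge is split
    in half; the suppressed node's two edges merge."""
    rng = _rng(rng)
    base_id = tree.canonical_id()
    adj, lengths = tree.adjacency()
    t = tree.n_tips
    # directed edges (u, v): prune subtree on v's side away from internal u
    candidates = [(u, v) for u in adj if len(adj[u]) == 3 for v in adj[u]]
    for _ in range(200):
        u, v = candidates[rng.integers(len(candidates))]
        a2 = {k: set(s) for k, s in adj.items()}
        ln2 = dict(lengths)
        pruned_len = ln2.pop(frozenset((u, v)))
        a2[u].discard(v)
        a2[v].discard(u)
        # suppress u: join its two remaining neighbors x, y
        x, y = sorted(a2[u])
        merged = frozenset((x, y))
        ln2[merged] = ln2.pop(frozenset((u, x))) + ln2.pop(frozenset((u, y)))
        a2[x].discard(u); a2[y].discard(u)
        a2[x].add(y); a2[y].add(x)
        del a2[u]
        # reachable component from v is the pruned subtree
        pruned = {v}
        stack = [v]
        while stack:
            w = stack.pop()
            for z in a2[w]:
                if z not in pruned:
                    pruned.add(z)
                    stack.append(z)
        host_edges = [e for e in ln2
                      if not (set(e) & pruned) and e != merged]
        if not host_edges:
            continue
        e = host_edges[rng.integers(len(host_edges))]
        p, q = sorted(e)
        half = ln2.pop(e) / 2.0
        a2[p].discard(q); a2[q].discard(p)
        a2[u] = set()
        for w, ln in ((p, half), (q, half), (v, pruned_len)):
            a2[u].add(w); a2[w].add(u)
            ln2[frozenset((u, w))] = ln
        out = TreeTopology.from_adjacency(tree.tip_labels, a2, ln2, rooted=False)
        if out.canonical_id() != base_id:
            return out
    raise TreeError("could not find a topology-changing SPR move")


def random_spr_neighbors(tree: TreeTopology, k: int, count: int, seed) -> list[TreeTopology]:
    """``count`` distinct topologies, each produced by ``k`` sequential
    random SPR moves from ``tree``; all outputs differ from the input and
    from each other."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if tree.n_tips < 4:
        raise TreeError("need >= 4 tips for SPR moves")
    rng = _rng(seed)
    seen = {tree.canonical_id()}
    out: list[TreeTopology] = []
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 200 * count + 200:
            raise TreeError(
                f"could not generate {count} distinct {k}-SPR neighbors; "
                "the neighborhood may be too small")
        cand = tree
        for _ in range(k):
            cand = spr_move(cand, rng)
        cid = cand.canonical_id()
        if cid not in seen:
            seen.add(cid)
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# 4-taxon coalescent with one introgression pulse


@dataclass
class IntrogressionSpec:
    """Species tree ``(((1,2),3),4)`` with divergence times in coalescent
    units, and a pulse at ``t_m`` in which the lineage sampled from species
    4 migrates into population 2 with probability ``r`` (looking backward
    in time).

    Defaults give substantial incomplete lineage sorting — the internal
    branch between the first two divergences is 0.5 coalescent units — on
    an old species tree, so that multiplying by the default
    substitutions-per-coalescent-unit factor of 0.002 yields primate-like
    terminal branch lengths of a few percent per site."""

    r: float = 0.0
    t_m: float = 0.5
    t12: float = 10.0
    t123: float = 10.5
    t1234: float = 15.0
    n_genes: int = 1500
    gene_length: int = 1000
    scale: float = 0.002
    seed: int | None = None
    tip_labels: tuple = ("t1", "t2", "t3", "t4")

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("introgression rate r must be in [0, 1]")
        if not (0.0 <= self.t_m < self.t12 < self.t123 < self.t1234):
            raise ValueError("need 0 <= t_m < t12 < t123 < t1234")


def sample_introgression_gene_trees(spec: IntrogressionSpec, seed=None) -> list[TreeTopology]:
    """Rooted gene trees with coalescent-unit branch lengths.

    At ``t_m`` the lineage ancestral to species 4 moves to population 2
    with probability ``r``; populations merge at the species divergence
    times; within a population every lineage pair coalesces at rate 1.
    """
    rng = _rng(spec.seed if seed is None else seed)
    labels = sorted(spec.tip_labels)
    trees = []
    for _ in range(spec.n_genes):
        trees.append(_one_gene_tree(spec, rng, labels))
    return trees


def _one_gene_tree(spec: IntrogressionSpec, rng, labels) -> TreeTopology:
    # lineage -> population; tips are 0..3 = sorted labels = species 1..4
    pop = {0: 1, 1: 2, 2: 3, 3: 4}
    node_time = {i: 0.0 for i in range(4)}
    parent: dict[int, int] = {}
    nxt = 4
    t_now = 0.0
    events = [(spec.t_m, "pulse"), (spec.t12, 12), (spec.t123, 123),
              (spec.t1234, 1234), (np.inf, None)]
    for t_event, kind in events:
        while len(pop) > 1:
            groups: dict[int, list[int]] = {}
            for lin, p in pop.items():
                groups.setdefault(p, []).append(lin)
            rate = sum(len(g) * (len(g) - 1) / 2 for g in groups.values())
            if rate == 0:
                break
            wait = rng.exponential(1.0 / rate)
            if t_now + wait >= t_event:
                break
            t_now += wait
            # choose the coalescing population proportional to its pair count
            pops, pr = zip(*[(p, len(g) * (len(g) - 1) / 2)
                             for p, g in groups.items() if len(g) > 1])
            p = pops[rng.choice(len(pops), p=np.array(pr) / sum(pr))]
            a, b = rng.choice(groups[p], size=2, replace=False)
            parent[a] = parent[b] = nxt
            node_time[nxt] = t_now
            pop[nxt] = p
            del pop[a], pop[b]
            nxt += 1
        if kind is None or len(pop) == 1:
            break
        t_now = t_event
        if kind == "pulse":
            for lin in list(pop):
                if pop[lin] == 4 and rng.random() < spec.r:
                    pop[lin] = 2
        elif kind == 12:
            for lin in pop:
                if pop[lin] == 2:
                    pop[lin] = 1
        elif kind == 123:
            for lin in pop:
                if pop[lin] == 3:
                    pop[lin] = 1
        elif kind == 1234:
            for lin in pop:
                pop[lin] = 1
    root = next(iter(pop))
    n = nxt
    parr = np.full(n, -1, dtype=np.int64)
    blen = np.full(n, np.nan)
    for c, p in parent.items():
        parr[c] = p
        blen[c] = node_time[p] - node_time[c]
    return TreeTopology(tip_labels=labels, parent=parr, lengths=blen, rooted=True)


def rescale_and_simulate_genes(gene_trees, model: ClassModel, seed,
                               scale: float = 0.002,
                               gene_length: int = 1000) -> Alignment:
    """Rescale coalescent-unit gene trees to substitutions/site by ``scale``,
    simulate ``gene_length`` sites per gene under ``model``'s GTR+G
    parameters, and concatenate."""
    rng = _rng(seed)
    chunks = []
    for gt in gene_trees:
        scaled = gt.with_lengths(np.where(np.isnan(gt.lengths), np.nan,
                                          gt.lengths * scale))
        cm = ClassModel(tree=scaled, gtr=model.gtr, freqs=model.freqs,
                        rhas=model.rhas)
        chunks.append(simulate_alignment(cm, gene_length, rng).data)
    first = gene_trees[0]
    return Alignment(taxon_labels=list(first.tip_labels),
                     data=np.concatenate(chunks, axis=1))


def quartet_topologies(tip_labels=("t1", "t2", "t3", "t4"),
                       branch_length: float = 0.05) -> list[TreeTopology]:
    """The three unrooted 4-taxon topologies, ordered: (12|34), (13|24),
    (14|23) with respect to the sorted tip labels."""
    a, b, c, d = sorted(tip_labels)
    nwk = [f"(({a}:{branch_length},{b}:{branch_length}):{branch_length},"
           f"{c}:{branch_length},{d}:{branch_length});",
           f"(({a}:{branch_length},{c}:{branch_length}):{branch_length},"
           f"{b}:{branch_length},{d}:{branch_length});",
           f"(({a}:{branch_length},{d}:{branch_length}):{branch_length},"
           f"{b}:{branch_length},{c}:{branch_length});"]
    return [TreeTopology.from_newick(s, rooted=False) for s in nwk]


def gene_tree_topology_index(gene_tree: TreeTopology) -> int:
    """0, 1 or 2 for the unrooted quartet class of a 4-taxon gene tree,
    in the order of :func:`quartet_topologies`."""
    refs = [t.canonical_id() for t in quartet_topologies(gene_tree.tip_labels)]
    return refs.index(gene_tree.unrooted().canonical_id())


def weight_rmse(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-squared error between matched weight vectors."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("weight vectors differ in length")
    return float(np.sqrt(np.mean((estimated - truth) ** 2)))
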