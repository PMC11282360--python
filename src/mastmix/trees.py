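"""Unrooted binary tree topologies with branch lengths.

Trees are stored with an arbitrary internal "handle" node of degree three
(degree two when the tree carries a true root, as coalescent gene trees do).
Topological identity is decided on the unrooted split set, so any two
rotations or rerootings of the same unrooted tree compare equal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

# Placeholder used when an input tree carries no branch lengths; real values
# come from parsimony initialization before any likelihood is computed.
DEFAULT_BRANCH_LENGTH = 0.1
MIN_BRANCH_LENGTH = 1e-6
MAX_BRANCH_LENGTH = 10.0


class TreeError(ValueError):
    pass


@dataclass
class TreeTopology:
    """A bifurcating tree topology with branch lengths (substitutions/site).

    Nodes are integers ``0..n_nodes-1``; tips come first, in the order of
    ``tip_labels``.  ``parent[v]`` is the parent of ``v`` under the current
    handle node (``-1`` at the handle), and ``lengths[v]`` is the length of
    the edge above ``v``.  An unrooted tree has a degree-3 handle, so there
    are ``2t - 3`` edges for ``t`` tips; a rooted tree has a degree-2 root
    and ``2t - 2`` edges.
    """

    tip_labels: list[str]
    parent: np.ndarray          # int array, n_nodes
    lengths: np.ndarray         # float array, n_nodes (nan above the handle)
    rooted: bool = False
    children: list[list[int]] = field(default_factory=list)
    root: int = -1

    def __post_init__(self):
        n = len(self.parent)
        if not self.children:
            ch: list[list[int]] = [[] for _ in range(n)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self.children = ch
        if self.root < 0:
            self.root = int(np.flatnonzero(self.parent < 0)[0])
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "TreeTopology":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree, rooted=rooted)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, rooted: bool | None = None) -> "TreeTopology":
        seed = dtree.seed_node
        nkids = len(seed.child_nodes())
        if rooted is None:
            rooted = nkids == 2
        if not rooted and nkids == 2:
            # collapse the artificial root of a rooted-form newick
            dtree.deroot()
            seed = dtree.seed_node

        tips = sorted(lf.taxon.label for lf in dtree.leaf_node_iter())
        if len(tips) != len(set(tips)):
            raise TreeError("duplicate tip labels in tree")
        tip_index = {lab: i for i, lab in enumerate(tips)}

        n_internal = sum(1 for nd in dtree.preorder_node_iter() if not nd.is_leaf())
        n = len(tips) + n_internal
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.full(n, np.nan)

        next_internal = len(tips)
        ids: dict[int, int] = {}
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                v = tip_index[nd.taxon.label]
            else:
                v = next_internal
                next_internal += 1
            ids[id(nd)] = v
            if nd.parent_node is not None:
                parent[v] = ids[id(nd.parent_node)]
                bl = nd.edge.length
                lengths[v] = DEFAULT_BRANCH_LENGTH if bl is None else float(bl)
        return cls(tip_labels=tips, parent=parent, lengths=lengths, rooted=rooted)

    def _validate(self):
        t = self.n_tips
        if t < 3 and not self.rooted:
            raise TreeError("unrooted trees need at least 3 tips")
        deg_root = len(self.children[self.root])
        want = 2 if self.rooted else 3
        if deg_root != want:
            raise TreeError(
                f"handle node has degree {deg_root}, expected {want} "
                f"({'rooted' if self.rooted else 'unrooted'} binary tree)")
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            if v < t:
                if self.children[v]:
                    raise TreeError("tip node has children")
            elif len(self.children[v]) != 2:
                raise TreeError("internal node is not bifurcating")

    # -- basic queries -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def edge_nodes(self) -> np.ndarray:
        """Child-side node of every edge (all nodes except the handle)."""
        return np.array([v for v in range(self.n_nodes) if v != self.root])

    def total_length(self) -> float:
        return float(np.nansum(self.lengths))

    def copy(self) -> "TreeTopology":
        return TreeTopology(
            tip_labels=list(self.tip_labels),
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            rooted=self.rooted,
        )

    def with_lengths(self, lengths: np.ndarray) -> "TreeTopology":
        t = self.copy()
        t.lengths = np.asarray(lengths, dtype=float).copy()
        return t

    # -- splits and identity ------------------------------------------

    def tipset_below(self) -> list[frozenset[str]]:
        """Tip-label set below each node (indexed by node)."""
        below: list[frozenset[str] | None] = [None] * self.n_nodes
        for v in self.postorder():
            if v < self.n_tips:
                below[v] = frozenset([self.tip_labels[v]])
            else:
                s: frozenset[str] = frozenset()
                for c in self.children[v]:
                    s |= below[c]  # type: ignore[operator]
                below[v] = s
        return below  # type: ignore[return-value]

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted splits, each as the side not holding the
        lexicographically smallest tip label."""
        all_tips = frozenset(self.tip_labels)
        ref = min(all_tips)
        out = set()
        below = self.tipset_below()
        for v in range(self.n_nodes):
            if v == self.root or v < self.n_tips:
                continue
            side = below[v]
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= self.n_tips - 2:
                out.add(side)
        return frozenset(out)

    def canonical_id(self) -> str:
        """Canonical topology string: equal iff unrooted split sets are equal."""
        parts = sorted(",".join(sorted(s)) for s in self.splits())
        return ";".join([",".join(sorted(self.tip_labels))] + parts)

    def rf_distance(self, other: "TreeTopology") -> int:
        if set(self.tip_labels) != set(other.tip_labels):
            raise TreeError("trees have different tip sets")
        a, b = self.splits(), other.splits()
        return len(a ^ b)

    # -- rerooting ------------------------------------------------------

    def rerooted(self, new_handle: int) -> "TreeTopology":
        """Return the same unrooted tree with the handle at another internal
        node.  Only valid for unrooted trees."""
        if self.rooted:
            raise TreeError("cannot rehandle a rooted tree")
        if new_handle < self.n_tips:
            raise TreeError("handle must be an internal node")
        if new_handle == self.root:
            return self.copy()
        parent = self.parent.copy()
        lengths = self.lengths.copy()
        # flip parent pointers along the path new_handle -> old root
        path = [new_handle]
        while parent[path[-1]] >= 0:
            path.append(int(parent[path[-1]]))
        for a, b in zip(path, path[1:]):
            # b was parent of a; now a is parent of b
            parent[b] = a
            lengths[b] = self.lengths[a]
        parent[new_handle] = -1
        lengths[new_handle] = np.nan
        return TreeTopology(tip_labels=list(self.tip_labels), parent=parent,
                            lengths=lengths, rooted=False)

    def unrooted(self) -> "TreeTopology":
        """Suppress a degree-2 root, merging its two child edges."""
        if not self.rooted:
            return self.copy()
        a, b = self.children[self.root]
        # keep the internal child (or b) as the surviving node; attach the
        # other under it with the summed length
        keep, move = (a, b) if a >= self.n_tips else (b, a)
        if keep < self.n_tips:
            raise TreeError("cannot unroot a 2-tip tree")
        parent = self.parent.copy()
        lengths = self.lengths.copy()
        parent[move] = keep
        lengths[move] = self.lengths[a] + self.lengths[b]
        # drop the old root node by compacting indices
        old_root = self.root
        parent[keep] = -1
        lengths[keep] = np.nan
        keepers = [v for v in range(self.n_nodes) if v != old_root]
        remap = {v: i for i, v in enumerate(keepers)}
        new_parent = np.array([remap[parent[v]] if parent[v] >= 0 else -1 for v in keepers])
        new_lengths = np.array([lengths[v] for v in keepers])
        return TreeTopology(tip_labels=list(self.tip_labels), parent=new_parent,
                            lengths=new_lengths, rooted=False)

    # -- adjacency view (for tree surgery) ------------------------------

    def adjacency(self):
        """Undirected adjacency dict and edge-length dict (frozenset keys).

        Tip nodes keep their indices 0..t-1 (aligned with ``tip_labels``)."""
        adj: dict[int, set[int]] = {v: set() for v in range(self.n_nodes)}
        lengths: dict[frozenset[int], float] = {}
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                adj[v].add(p)
                adj[p].add(v)
                lengths[frozenset((v, p))] = float(self.lengths[v])
        return adj, lengths

    @classmethod
    def from_adjacency(cls, tip_labels: list[str], adj: dict[int, set[int]],
                       lengths: dict[frozenset[int], float],
                       rooted: bool = False) -> "TreeTopology":
        """Build a tree from an undirected adjacency structure whose tip
        nodes are 0..t-1 in the order of sorted ``tip_labels``."""
        tips = sorted(tip_labels)
        t = len(tips)
        want_deg = 2 if rooted else 3
        handle = next(v for v in adj if v >= t and len(adj[v]) == want_deg)
        remap = {}
        nxt = t
        parent_raw: dict[int, int] = {}
        seen = {handle}
        queue = [handle]
        while queue:
            v = queue.pop(0)
            remap[v] = v if v < t else nxt
            if v >= t:
                nxt += 1
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    parent_raw[w] = v
                    queue.append(w)
        parent = np.full(nxt, -1, dtype=np.int64)
        blen = np.full(nxt, np.nan)
        for w, v in parent_raw.items():
            parent[remap[w]] = remap[v]
            blen[remap[w]] = lengths[frozenset((w, v))]
        return cls(tip_labels=tips, parent=parent, lengths=blen, rooted=rooted)

    # -- newick ---------------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                base = self.tip_labels[v]
            else:
                base = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if include_lengths and v != self.root:
                base += f":{self.lengths[v]:.10g}"
            return base
        return rec(self.root) + ";"

    def __eq__(self, other) -> bool:  # topological identity only
        if not isinstance(other, TreeTopology):
            return NotImplemented
        return self.canonical_id() == other.canonical_id()

    def __hash__(self) -> int:
        return hash(self.canonical_id())


def random_topology(tip_labels: list[str], rng: np.random.Generator,
                    branch_lengths=None) -> TreeTopology:
    """Uniform random unrooted binary topology by sequential tip addition.

    Each new tip is attached to an edge chosen uniformly at random, which
    yields the uniform distribution over unrooted binary topologies.
    ``branch_lengths`` may be a callable ``rng -> float`` used to draw each
    edge length; default is the placeholder length everywhere.
    """
    tips = sorted(tip_labels)
    t = len(tips)
    if t < 4:
        raise TreeError("need at least 4 tips for a random unrooted topology")
    draw = branch_lengths if branch_lengths is not None else (lambda r: DEFAULT_BRANCH_LENGTH)

    # adjacency representation while building
    nodes = list(range(t))
    adj: dict[int, set[int]] = {i: set() for i in range(t)}
    nxt = t

    def connect(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def disconnect(a, b):
        adj[a].discard(b)
        adj[b].discard(a)

    # start from the 3-tip star
    star = nxt; nxt += 1
    for i in range(3):
        connect(star, i)
    edges = [(star, 0), (star, 1), (star, 2)]
    for tip in range(3, t):
        a, b = edges[rng.integers(len(edges))]
        disconnect(a, b)
        mid = nxt; nxt += 1
        connect(a, mid); connect(mid, b); connect(mid, tip)
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
    lengths = {frozenset((u, v)): draw(rng) for u, v in edges}
    return TreeTopology.from_adjacency(tips, adj, lengths, rooted=False)


def enumerate_topologies(tip_labels: list[str],
                         branch_length: float = DEFAULT_BRANCH_LENGTH) -> list[TreeTopology]:
    """All unrooted binary topologies on the given tips, by recursive tip
    addition over every edge ((2t-5)!! trees; intended for small t)."""
    tips = sorted(tip_labels)
    t = len(tips)
    if t < 4:
        raise TreeError("enumeration needs at least 4 tips")
    if t > 8:
        raise TreeError("refusing to enumerate topologies for more than 8 tips")

    def grow(adj: dict[int, set[int]], nxt: int, tip: int):
        if tip == t:
            lengths = {frozenset((u, v)): branch_length
                       for u in adj for v in adj[u] if u < v}
            yield TreeTopology.from_adjacency(tips, adj, lengths, rooted=False)
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for a, b in edges:
            a2 = {k: set(s) for k, s in adj.items()}
            a2[a].discard(b); a2[b].discard(a)
            mid = nxt
            a2[mid] = {a, b, tip}
            a2[a].add(mid); a2[b].add(mid)
            a2[tip] = {mid}
            yield from grow(a2, nxt + 1, tip + 1)

    star = {t: {0, 1, 2}, 0: {t}, 1: {t}, 2: {t}}
    # internal nodes get indices >= t; reserve t for the star center and
    # start fresh internals at 2t to avoid collisions with tips
    adj0 = {(2 * t if k == t else k): ({2 * t} if k != t else set(v))
            for k, v in star.items()}
    adj0[2 * t] = {0, 1, 2}
    return list(grow(adj0, 2 * t + 1, 3))


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
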