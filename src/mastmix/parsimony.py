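"""Fitch parsimony: site scores, starting branch lengths, starting weights.

Parsimony is only used to seed the likelihood optimization: branch lengths
start at changes-per-site attributed by one minimal Fitch reconstruction,
and tree weights start at the proportions of parsimony-discriminating sites
assigned to each topology (equal weights if no site discriminates).

Ambiguity codes enter as their compatible state sets, which the bitmask
alignment encoding gives us for free.  The degree-3 handle node is scored
by rooting on the edge above its last child, which leaves the unrooted
parsimony score unchanged.
"""

from __future__ import annotations

import numpy as np

from .alignment import PatternAlignment
from .trees import TreeTopology

# lowest set bit of a 4-bit mask (0 maps to 0)
_LOWBIT = np.array([m & (-m) for m in range(16)], dtype=np.uint8)


def _tip_row_map(tree: TreeTopology, paln: PatternAlignment) -> np.ndarray:
    rows = {lab: i for i, lab in enumerate(paln.taxon_labels)}
    return np.array([rows[lab] for lab in tree.tip_labels])


def fitch_pattern_scores(paln: PatternAlignment, tree: TreeTopology) -> np.ndarray:
    """Minimum number of state changes for every pattern (int array)."""
    scores, _ = _fitch_sets(paln, tree)
    return scores


def _fitch_sets(paln: PatternAlignment, tree: TreeTopology):
    """Bottom-up Fitch pass.  Returns (scores, sets) where ``sets[v]`` is the
    Fitch state set of node ``v`` per pattern; the handle's three subtrees
    are combined pairwise (equivalent to rooting on the third child's edge)."""
    P = paln.n_patterns
    tip_rows = _tip_row_map(tree, paln)
    sets = np.zeros((tree.n_nodes, P), dtype=np.uint8)
    scores = np.zeros(P, dtype=np.int64)
    for v in tree.postorder():
        if v < tree.n_tips:
            sets[v] = paln.patterns[tip_rows[v]]
            continue
        kids = tree.children[v]
        acc = sets[kids[0]]
        for c in kids[1:]:
            inter = acc & sets[c]
            disjoint = inter == 0
            scores += disjoint
            acc = np.where(disjoint, acc | sets[c], inter)
        sets[v] = acc
    return scores, sets


def fitch_parsimony_score(pattern_scores: np.ndarray, weights: np.ndarray) -> int:
    """Total tree parsimony score over the alignment."""
    return int(np.dot(pattern_scores, weights))


def fitch_branch_changes(paln: PatternAlignment, tree: TreeTopology) -> np.ndarray:
    """Changes attributed to each edge (indexed by child node) under one
    minimal Fitch reconstruction, summed over sites.

    Top-down resolution: a child keeps the parent state when compatible,
    otherwise any of its own Fitch states is chosen and one change is
    charged to that child's edge.  A degree-3 handle is resolved through
    the virtual binary rooting used for scoring (first two children
    combined into an intermediate set); the change across the rooting edge,
    if any, is charged to the third child's edge.  Totals over branches
    equal the Fitch score of every site."""
    _, sets = _fitch_sets(paln, tree)
    P = paln.n_patterns
    w = paln.weights
    changes = np.zeros(tree.n_nodes, dtype=np.float64)
    state = np.zeros((tree.n_nodes, P), dtype=np.uint8)
    root = tree.root
    kids = tree.children[root]

    def resolve(child, parent_state, charge_node):
        keep = (parent_state & sets[child]) > 0
        state[child] = np.where(keep, parent_state, _LOWBIT[sets[child]])
        changes[charge_node] += float(np.dot((~keep).astype(np.int64), w))

    if len(kids) == 3:
        # virtual binary root on the edge above kids[2]
        s12 = sets[kids[0]] & sets[kids[1]]
        s12 = np.where(s12 == 0, sets[kids[0]] | sets[kids[1]], s12)
        root_state = _LOWBIT[sets[root]]
        # both halves of the rooting edge charge the third child's edge
        keep12 = (root_state & s12) > 0
        state12 = np.where(keep12, root_state, _LOWBIT[s12])
        changes[kids[2]] += float(np.dot((~keep12).astype(np.int64), w))
        resolve(kids[2], root_state, kids[2])
        resolve(kids[0], state12, kids[0])
        resolve(kids[1], state12, kids[1])
    else:  # rooted (binary) trees
        state[root] = _LOWBIT[sets[root]]
        for c in kids:
            resolve(c, state[root], c)

    for u in reversed(tree.postorder()):  # preorder
        if u < tree.n_tips or u == root:
            continue
        for c in tree.children[u]:
            resolve(c, state[u], c)
    return changes


def initialize_branch_lengths(paln: PatternAlignment, tree: TreeTopology,
                              min_branch: float = 1e-6,
                              max_branch: float = 10.0) -> TreeTopology:
    """Starting branch lengths: attributed parsimony changes per site."""
    changes = fitch_branch_changes(paln, tree)
    lengths = changes / paln.n_sites
    lengths = np.clip(lengths, min_branch, max_branch)
    lengths[tree.root] = np.nan
    return tree.with_lengths(lengths)


def initialize_weights(paln: PatternAlignment, trees,
                       weight_floor: float = 1e-6) -> np.ndarray:
    """Starting tree weights from parsimony-discriminating sites.

    Sites whose parsimony scores differ between trees are assigned to the
    minimum-score tree(s); ties are split fractionally so the totals
    conserve the discriminating-site count.  If no site discriminates (or
    there is a single tree) weights start equal."""
    m = len(trees)
    if m == 1:
        return np.array([1.0])
    S = np.column_stack([fitch_pattern_scores(paln, t) for t in trees])  # (P, m)
    discriminating = ~(S == S[:, :1]).all(axis=1)
    if not discriminating.any():
        return np.full(m, 1.0 / m)
    Sd = S[discriminating]
    wd = paln.weights[discriminating].astype(float)
    is_min = Sd == Sd.min(axis=1, keepdims=True)
    share = is_min / is_min.sum(axis=1, keepdims=True)
    counts = share.T @ wd
    w = counts / counts.sum()
    w = np.maximum(w, weight_floor)
    return w / w.sum()
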