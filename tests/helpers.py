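"""Shared helpers and independent oracles for the test suite.

The brute-force likelihood oracle enumerates all joint internal-node state
assignments, so it is exponential in tree size and deliberately shares no
code with the pruning engine beyond the rate-matrix builder (which is
itself checked elementwise elsewhere).
"""

from __future__ import annotations

import itertools

import numpy as np

import mastmix as mm
from mastmix.alignment import compress_patterns


def random_class_model(rng, n_tips=5, ncat=4, alpha_range=(0.3, 2.0),
                       bl_range=(0.02, 0.5)):
    tips = [f"t{i}" for i in range(n_tips)]
    tree = mm.random_topology(
        tips, rng, branch_lengths=lambda r: r.uniform(*bl_range))
    gtr = mm.GTRParams(np.append(np.exp(rng.uniform(-1.2, 1.2, 5)), 1.0))
    freqs = mm.BaseFrequencies(rng.dirichlet(np.full(4, 10.0)))
    rhas = (mm.discretize_gamma(rng.uniform(*alpha_range), ncat)
            if ncat > 1 else mm.GammaRHAS.none())
    return mm.ClassModel(tree, gtr, freqs, rhas)


def brute_force_pattern_logliks(paln, cm):
    """Exhaustive sum over all internal-node state assignments, averaged
    over gamma categories; independent of the pruning code path."""
    tree = cm.tree
    Q = mm.build_rate_matrix(cm.gtr, cm.freqs)
    rates = cm.rhas.category_rates
    tipp = paln.tip_partials()
    rowmap = {lab: i for i, lab in enumerate(paln.taxon_labels)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    out = np.zeros(paln.n_patterns)
    for p in range(paln.n_patterns):
        total = 0.0
        for rate in rates:
            P = {v: Q.transition(float(tree.lengths[v]), rate)
                 for v in range(tree.n_nodes) if v != tree.root}
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                pr = cm.freqs.pi[amap[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    parent_state = amap[tree.parent[v]]
                    if v < tree.n_tips:
                        partial = tipp[rowmap[tree.tip_labels[v]], p]
                        pr *= float(P[v][parent_state] @ partial)
                    else:
                        pr *= P[v][parent_state, amap[v]]
                s += pr
            total += s / len(rates)
        out[p] = np.log(total)
    return out


def small_pattern_alignment(cm, n_sites, seed):
    aln = mm.simulate_alignment(cm, n_sites, seed)
    return compress_patterns(aln)
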