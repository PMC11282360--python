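"""Fitch scores against brute force, branch-change conservation, and the
parsimony-based weight initialization."""

import itertools

import numpy as np
import pytest

import mastmix as mm
from mastmix.alignment import Alignment, compress_patterns
from mastmix.parsimony import (fitch_pattern_scores, fitch_branch_changes,
                               initialize_branch_lengths, initialize_weights)


def brute_force_fitch(paln, tree):
    """Minimum changes over all internal-node labelings; independent of the
    set-based Fitch pass."""
    masks = paln.patterns
    rowmap = {lab: i for i, lab in enumerate(paln.taxon_labels)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    out = np.zeros(paln.n_patterns, dtype=int)
    for p in range(paln.n_patterns):
        best = 10 ** 9
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            cost = 0
            ok = True
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                pstate = amap[tree.parent[v]]
                if v < tree.n_tips:
                    mask = masks[rowmap[tree.tip_labels[v]], p]
                    if not (mask >> pstate) & 1:
                        # tip must take a compatible state; cheapest is one
                        # change if the parent state is incompatible
                        cost += 1
                    if mask == 0:
                        ok = False
                else:
                    cost += pstate != amap[v]
            if ok:
                best = min(best, cost)
        out[p] = best
    return out


class TestFitchScores:
    def test_constant_column_scores_zero(self):
        tree = mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);")
        aln = Alignment.from_records([(x, "A") for x in "abcd"])
        paln = compress_patterns(aln)
        assert fitch_pattern_scores(paln, tree).tolist() == [0]

    def test_single_informative_change(self):
        tree = mm.TreeTopology.from_newick("((a1:1,a2:1):1,c1:1,c2:1);")
        aln = Alignment.from_records(
            [("a1", "A"), ("a2", "A"), ("c1", "C"), ("c2", "C")])
        paln = compress_patterns(aln)
        assert fitch_pattern_scores(paln, tree).tolist() == [1]

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_exhaustive_minimization(self, trial):
        rng = np.random.default_rng(300 + trial)
        tree = mm.random_topology([f"t{i}" for i in range(5)], rng)
        chars = rng.choice(list("ACGTRYN-"), size=(5, 30))
        aln = Alignment.from_records(
            [(f"t{i}", "".join(chars[i])) for i in range(5)])
        paln = compress_patterns(aln)
        fast = fitch_pattern_scores(paln, tree)
        slow = brute_force_fitch(paln, tree)
        assert fast.tolist() == slow.tolist()

    def test_branch_changes_conserve_total_score(self, rng):
        tree = mm.random_topology([f"t{i}" for i in range(6)], rng)
        cm = mm.ClassModel(tree.with_lengths(np.where(np.isnan(tree.lengths),
                                                      np.nan, 0.3)),
                           mm.GTRParams.jc(), mm.BaseFrequencies.uniform(),
                           mm.GammaRHAS.none())
        paln = compress_patterns(mm.simulate_alignment(cm, 120, rng))
        per_branch = fitch_branch_changes(paln, tree)
        total = float(np.dot(fitch_pattern_scores(paln, tree), paln.weights))
        assert per_branch.sum() == pytest.approx(total)


class TestInitialization:
    def test_identical_sequences_floor_branch_lengths(self):
        tree = mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);")
        aln = Alignment.from_records([(x, "ACGT" * 5) for x in "abcd"])
        paln = compress_patterns(aln)
        out = initialize_branch_lengths(paln, tree, min_branch=1e-6)
        lengths = out.lengths[out.edge_nodes()]
        assert np.allclose(lengths, 1e-6)

    def test_internal_branch_equals_discriminating_site_fraction(self):
        # 4 informative AACC-type columns among 20: the internal edge takes
        # exactly those 4 changes, so its length starts at 4/20
        tree = mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);")
        seqs = {"a": "A" * 16 + "AAAA", "b": "A" * 16 + "AAAA",
                "c": "A" * 16 + "CCCC", "d": "A" * 16 + "CCCC"}
        paln = compress_patterns(Alignment.from_records(list(seqs.items())))
        out = initialize_branch_lengths(paln, tree, min_branch=1e-6)
        internal = [v for v in out.edge_nodes() if v >= out.n_tips]
        assert out.lengths[internal].sum() == pytest.approx(4 / 20, abs=1e-9)

    def test_all_ties_give_equal_weights(self):
        trees = [mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);"),
                 mm.TreeTopology.from_newick("((a:1,c:1):1,b:1,d:1);")]
        aln = Alignment.from_records([(x, "AAAA") for x in "abcd"])
        paln = compress_patterns(aln)
        assert initialize_weights(paln, trees).tolist() == [0.5, 0.5]

    def test_discriminating_site_proportions(self):
        t1 = mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);")
        t2 = mm.TreeTopology.from_newick("((a:1,c:1):1,b:1,d:1);")
        # 30 sites favor t1 (AABB pattern), 10 favor t2 (ABAB), 20 tie
        seqs = {"a": "A" * 30 + "A" * 10 + "A" * 20,
                "b": "A" * 30 + "C" * 10 + "C" * 20,
                "c": "C" * 30 + "A" * 10 + "G" * 20,
                "d": "C" * 30 + "C" * 10 + "T" * 20}
        paln = compress_patterns(Alignment.from_records(list(seqs.items())))
        w = initialize_weights(paln, [t1, t2])
        assert w.tolist() == pytest.approx([0.75, 0.25])

    def test_shared_minimum_splits_fractionally(self):
        t1 = mm.TreeTopology.from_newick("((a:1,b:1):1,c:1,d:1);")
        t2 = mm.TreeTopology.from_newick("((a:1,c:1):1,b:1,d:1);")
        t3 = mm.TreeTopology.from_newick("((a:1,d:1):1,b:1,c:1);")
        # AABB: t1 scores 1, t2 and t3 score 2 -> site assigned wholly to t1.
        # ABAB: t2 scores 1, others 2 -> wholly to t2.  ABBA: wholly to t3.
        # AABB+ABAB mix with equal counts conserves the discriminating total.
        seqs = {"a": "AAAA", "b": "AACC", "c": "CCAA", "d": "CCCC"}
        paln = compress_patterns(Alignment.from_records(list(seqs.items())))
        w = initialize_weights(paln, [t1, t2, t3])
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > w[2] and w[1] > w[2]
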