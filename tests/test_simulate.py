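"""Sequence and coalescent simulators: reproducibility, composition,
mixture labels, gene-tree frequencies against the coalescent closed form."""

import numpy as np
import pytest

import mastmix as mm
from mastmix.simulate import (IntrogressionSpec, MixtureSimSpec,
                              gene_tree_topology_index,
                              sample_introgression_gene_trees,
                              rescale_and_simulate_genes, simulate_mixture,
                              quartet_topologies, weight_rmse)
from helpers import random_class_model


class TestSimulateAlignment:
    def test_dimensions_and_tipset(self, rng):
        cm = random_class_model(rng, n_tips=6)
        aln = mm.simulate_alignment(cm, 123, rng)
        assert aln.n_sites == 123
        assert aln.taxon_labels == cm.tree.tip_labels

    def test_seed_reproducibility(self, rng):
        cm = random_class_model(rng, n_tips=5)
        a = mm.simulate_alignment(cm, 300, 11)
        b = mm.simulate_alignment(cm, 300, 11)
        c = mm.simulate_alignment(cm, 300, 12)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_long_branches_reach_stationary_composition(self, rng):
        tips = [f"t{i}" for i in range(4)]
        tree = mm.random_topology(tips, rng, branch_lengths=lambda r: 50.0)
        freqs = mm.BaseFrequencies(np.array([0.4, 0.25, 0.2, 0.15]))
        cm = mm.ClassModel(tree, mm.GTRParams.jc(), freqs, mm.GammaRHAS.none())
        n = 4000
        aln = mm.simulate_alignment(cm, n, rng)
        bits = {1: 0, 2: 1, 4: 2, 8: 3}
        for row in aln.data:
            counts = np.bincount([bits[b] for b in row], minlength=4) / n
            se = np.sqrt(freqs.pi * (1 - freqs.pi) / n)
            assert np.all(np.abs(counts - freqs.pi) < 4 * se)


class TestSimulateMixture:
    def test_block_mode_labels(self, rng):
        cms = [random_class_model(rng, n_tips=4) for _ in range(2)]
        cms[1].tree = cms[0].tree  # same tip set required
        aln, labels = simulate_mixture(MixtureSimSpec(
            classes=cms, n_sites=80, block_lengths=[45, 35], mode="block",
            seed=3))
        assert labels.tolist() == [0] * 45 + [1] * 35
        assert aln.n_sites == 80

    def test_iid_mode_binomial_bound(self, rng):
        cms = [random_class_model(rng, n_tips=4) for _ in range(2)]
        cms[1].tree = cms[0].tree
        n = 20000
        aln, labels = simulate_mixture(MixtureSimSpec(
            classes=cms, n_sites=n, weights=np.array([0.5, 0.5]), seed=4))
        frac = (labels == 0).mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_single_class_weight_one(self, rng):
        cm = random_class_model(rng, n_tips=4)
        aln, labels = simulate_mixture(MixtureSimSpec(
            classes=[cm], n_sites=50, weights=np.array([1.0]), seed=5))
        assert set(labels.tolist()) == {0}

    def test_spec_validation(self, rng):
        cm = random_class_model(rng, n_tips=4)
        with pytest.raises(ValueError):
            MixtureSimSpec(classes=[cm], n_sites=10, mode="block",
                           block_lengths=[5])
        with pytest.raises(ValueError):
            MixtureSimSpec(classes=[cm], n_sites=10,
                           weights=np.array([0.5, 0.5]))


class TestWeightRmse:
    def test_examples(self):
        assert weight_rmse([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert weight_rmse([0.5, 0.5], [0.6, 0.4]) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            weight_rmse([0.5], [0.5, 0.5])

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a, b = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
            want = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 4)
            assert weight_rmse(a, b) == pytest.approx(want)


class TestCoalescentIntrogression:
    def test_no_introgression_matches_closed_form(self):
        # minor-tree probability is (1/3) e^{-T} for internal branch T;
        # a distant outgroup keeps the fourth lineage out of the way
        spec = IntrogressionSpec(r=0.0, t12=1.0, t123=1.5, t1234=12.0,
                                 n_genes=4000)
        gts = sample_introgression_gene_trees(spec, seed=77)
        counts = np.bincount([gene_tree_topology_index(g) for g in gts],
                             minlength=3)
        p_minor = (1 / 3) * np.exp(-0.5)
        se = np.sqrt(p_minor * (1 - p_minor) / spec.n_genes)
        assert abs(counts[1] / spec.n_genes - p_minor) < 4 * se
        assert abs(counts[2] / spec.n_genes - p_minor) < 4 * se
        assert counts[0] > counts[1] and counts[0] > counts[2]

    def test_te2_fraction_increases_with_introgression(self):
        fracs = []
        for r in (0.0, 0.5, 1.0):
            spec = IntrogressionSpec(r=r, n_genes=1200)
            gts = sample_introgression_gene_trees(spec, seed=88)
            idx = [gene_tree_topology_index(g) for g in gts]
            fracs.append(np.mean(np.array(idx) == 1))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_gene_trees_are_rooted_ultrametric_enough(self):
        spec = IntrogressionSpec(r=0.3, n_genes=20)
        for gt in sample_introgression_gene_trees(spec, seed=9):
            assert gt.rooted
            assert gt.n_tips == 4
            assert np.all(gt.lengths[~np.isnan(gt.lengths)] >= 0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            IntrogressionSpec(r=1.5)
        with pytest.raises(ValueError):
            IntrogressionSpec(t_m=12.0)  # after the first divergence


class TestRescaleAndSimulate:
    def test_concatenated_length(self):
        spec = IntrogressionSpec(r=0.0, n_genes=10)
        gts = sample_introgression_gene_trees(spec, seed=1)
        model = mm.ClassModel(quartet_topologies()[0], mm.GTRParams.jc(),
                              mm.BaseFrequencies.uniform(), mm.GammaRHAS.none())
        aln = rescale_and_simulate_genes(gts, model, seed=2, scale=0.002,
                                         gene_length=100)
        assert aln.n_sites == 1000
        assert sorted(aln.taxon_labels) == ["t1", "t2", "t3", "t4"]

    def test_zero_scale_gives_identical_sequences(self):
        spec = IntrogressionSpec(r=0.0, n_genes=3)
        gts = sample_introgression_gene_trees(spec, seed=1)
        model = mm.ClassModel(quartet_topologies()[0], mm.GTRParams.jc(),
                              mm.BaseFrequencies.uniform(), mm.GammaRHAS.none())
        aln = rescale_and_simulate_genes(gts, model, seed=2, scale=0.0,
                                         gene_length=50)
        assert np.all(aln.data == aln.data[0])

    def test_linear_scaling_of_total_length(self):
        spec = IntrogressionSpec(r=0.0, n_genes=1)
        gt = sample_introgression_gene_trees(spec, seed=1)[0]
        scaled = gt.with_lengths(gt.lengths * 0.002)
        assert scaled.total_length() == pytest.approx(0.002 * gt.total_length())


class TestQuartetHelpers:
    def test_three_distinct_topologies(self):
        ids = {t.canonical_id() for t in quartet_topologies()}
        assert len(ids) == 3

    def test_topology_index_round_trip(self):
        for i, t in enumerate(quartet_topologies()):
            assert gene_tree_topology_index(t) == i
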