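"""Fitting workflow: parameter counting, BIC, EM weight updates, and
small end-to-end fits with their invariants."""

import math

import numpy as np
import pytest

import mastmix as mm
from mastmix.alignment import compress_patterns
from mastmix.inference import SUBMODEL_LINKAGE, optimize_weights
from mastmix.likelihood import site_log_likelihood_matrix
from mastmix.simulate import MixtureSimSpec, simulate_mixture
from helpers import random_class_model


QUICK = mm.MastConfig(submodel=1, ncat=2, joint_maxiter=200)


class TestParameterCounting:
    def test_fully_linked_three_class_example(self):
        # 2 weights + 3*(2*4-3)=15 branches + 5 + 3 + 1 shared
        assert mm.count_free_parameters(6, m=3, t=4) == 26

    def test_fully_unlinked_two_class_example(self):
        # 1 + 2*(2*6-3)=18 + 2*5 + 2*3 + 2*1
        assert mm.count_free_parameters(1, m=2, t=6) == 37

    def test_single_class_matches_single_tree_model(self):
        for sub in range(1, 7):
            assert mm.count_free_parameters(sub, 1, 8) == \
                mm.count_free_parameters(6, 1, 8)

    def test_linkage_table_has_no_linked_rates_with_unlinked_freqs(self):
        for rl, fl, hl in SUBMODEL_LINKAGE.values():
            assert not (rl and not fl)

    def test_no_rhas_parameter_when_single_category(self):
        assert mm.count_free_parameters(1, 2, 5, ncat=1) == \
            mm.count_free_parameters(1, 2, 5, ncat=4) - 2


class TestBic:
    def test_arithmetic(self):
        assert mm.bic(-1000.0, 5, 100) == pytest.approx(2000 + 5 * math.log(100))

    def test_monotone_in_parameters_and_likelihood(self):
        assert mm.bic(-1000, 6, 100) > mm.bic(-1000, 5, 100)
        assert mm.bic(-1001, 5, 100) > mm.bic(-1000, 5, 100)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            mm.bic(-10, 2, 0)


class TestWeightUpdates:
    def test_hard_posterior_average(self):
        post = np.array([[1.0, 0], [0, 1.0], [1.0, 0]])
        w = mm.em_update_weights(post, np.ones(3))
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_uniform_posterior_is_fixed_point(self):
        post = np.full((5, 2), 0.5)
        assert mm.em_update_weights(post, np.ones(5)).tolist() == [0.5, 0.5]

    def test_pattern_weighted_column_mean_oracle(self, rng):
        post = rng.dirichlet(np.ones(3), size=8)
        pw = rng.integers(1, 9, size=8)
        w = mm.em_update_weights(post, pw, weight_floor=0.0)
        want = (pw[:, None] * post).sum(0) / pw.sum()
        assert np.allclose(w, want / want.sum())

    def test_floor_keeps_weights_positive(self):
        post = np.column_stack([np.ones(4), np.zeros(4)])
        w = mm.em_update_weights(post, np.ones(4), weight_floor=1e-6)
        assert w[1] >= 0.99e-6 and w.sum() == pytest.approx(1.0)


def _two_class_data(rng, n_sites=1500, n_taxa=6):
    from mastmix.experiments import (sample_mixture_topologies,
                                     sample_mixture_classes)
    trees = sample_mixture_topologies(n_taxa, 2, rng)
    classes = sample_mixture_classes(trees, linked=False, rng=rng)
    w = np.array([0.75, 0.25])
    aln, _ = simulate_mixture(MixtureSimSpec(
        classes=classes, n_sites=n_sites, weights=w, seed=rng))
    return aln, trees, classes, w


class TestFitMast:
    def test_trace_monotone_and_converged(self, rng):
        aln, trees, _, _ = _two_class_data(rng)
        fit = mm.fit_mast(aln, trees, QUICK)
        assert fit.converged
        assert all(b >= a for a, b in zip(fit.trace, fit.trace[1:]))
        assert fit.trace[-1] - fit.trace[-2] < QUICK.epsilon

    def test_single_class_parity_with_single_tree_fit(self, rng):
        cm = random_class_model(rng, n_tips=5, ncat=2)
        aln = mm.simulate_alignment(cm, 1200, rng)
        f1 = mm.fit_mast(aln, [cm.tree], QUICK)
        f2 = mm.fit_single_tree(aln, cm.tree, QUICK)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-2)
        assert f1.n_free_params == f2.n_free_params

    def test_pure_class_one_data_pushes_weight_to_one(self, rng):
        cm = random_class_model(rng, n_tips=6, ncat=2)
        aln = mm.simulate_alignment(cm, 4000, rng)
        from mastmix.simulate import random_spr_neighbors
        decoy = random_spr_neighbors(cm.tree, k=2, count=1, seed=rng)[0]
        fit = mm.fit_mast(aln, [cm.tree, decoy], QUICK)
        assert fit.weights[0] > 0.9

    def test_identical_topologies_match_single_tree_likelihood(self, rng):
        """Degenerate mixture: two copies of one topology under the fully
        linked submodel cannot beat the single-tree likelihood."""
        cm = random_class_model(rng, n_tips=5, ncat=2)
        aln = mm.simulate_alignment(cm, 800, rng)
        cfg = mm.MastConfig(submodel=6, ncat=2, joint_maxiter=200)
        fit2 = mm.fit_mast(aln, [cm.tree, cm.tree.copy()], cfg)
        fit1 = mm.fit_single_tree(aln, cm.tree, cfg)
        assert fit2.log_likelihood == pytest.approx(fit1.log_likelihood, abs=0.05)

    def test_weight_fixed_point_is_conditional_optimum(self, rng):
        aln, trees, classes, _ = _two_class_data(rng, n_sites=600)
        paln = compress_patterns(aln)
        L = site_log_likelihood_matrix(paln, classes)
        w_star = optimize_weights(L, np.array([0.5, 0.5]))
        from mastmix.likelihood import total_log_likelihood
        base = total_log_likelihood(L, w_star)
        for delta in (0.01, -0.01, 0.05):
            w = np.clip(w_star + [delta, -delta], 1e-9, None)
            w = w / w.sum()
            assert total_log_likelihood(L, w) <= base + 1e-9

    def test_submodels_share_linked_blocks(self, rng):
        aln, trees, _, _ = _two_class_data(rng, n_sites=800)
        cfg = mm.MastConfig(submodel=6, ncat=2, joint_maxiter=150)
        fit = mm.fit_mast(aln, trees, cfg)
        a, b = fit.classes
        assert a.gtr is b.gtr and a.freqs is b.freqs and a.rhas is b.rhas
        cfg1 = mm.MastConfig(submodel=1, ncat=2, joint_maxiter=150)
        fit1 = mm.fit_mast(aln, trees, cfg1)
        a, b = fit1.classes
        assert a.gtr is not b.gtr

    def test_invalid_inputs(self, rng):
        aln, trees, _, _ = _two_class_data(rng, n_sites=100)
        with pytest.raises(ValueError):
            mm.fit_mast(aln, [], QUICK)
        with pytest.raises(ValueError):
            mm.MastConfig(submodel=7)
        with pytest.raises(ValueError):
            mm.MastConfig(epsilon=0)


class TestSingleTree:
    def test_jc_data_recovers_near_unit_exchangeabilities(self, rng):
        tips = [f"t{i}" for i in range(5)]
        tree = mm.random_topology(tips, rng,
                                  branch_lengths=lambda r: r.uniform(0.05, 0.3))
        cm = mm.ClassModel(tree, mm.GTRParams.jc(), mm.BaseFrequencies.uniform(),
                           mm.GammaRHAS.none())
        aln = mm.simulate_alignment(cm, 20000, rng)
        fit = mm.fit_single_tree(aln, tree, mm.MastConfig(ncat=1))
        rates = fit.classes[0].gtr.rates
        assert np.all(np.abs(np.log(rates)) < np.log(1.35))
        assert np.allclose(fit.classes[0].freqs.pi, 0.25, atol=0.02)

    def test_loglik_invariant_to_input_rooting(self, rng):
        cm = random_class_model(rng, n_tips=6, ncat=2)
        aln = mm.simulate_alignment(cm, 500, rng)
        cfg = mm.MastConfig(ncat=2)
        f1 = mm.fit_single_tree(aln, cm.tree, cfg)
        f2 = mm.fit_single_tree(aln, cm.tree.rerooted(cm.tree.n_nodes - 1), cfg)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=5e-3)
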