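"""Pruning likelihoods against exhaustive enumeration, mixture formulas,
posteriors, and the analytic gradients."""

import math

import numpy as np
import pytest

import mastmix as mm
from mastmix.alignment import compress_patterns
from mastmix.likelihood import (SiteLikelihoodMatrix, class_loglik_and_gradients,
                                weighted_loglik_and_branch_grad)
from helpers import (random_class_model, brute_force_pattern_logliks,
                       small_pattern_alignment)


class TestPruningOracle:
    @pytest.mark.parametrize("trial", range(6))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        cm = random_class_model(rng, n_tips=int(rng.integers(4, 6)),
                                ncat=int(rng.integers(1, 4)))
        paln = small_pattern_alignment(cm, 25, rng)
        fast = mm.class_site_log_likelihoods(paln, cm)
        slow = brute_force_pattern_logliks(paln, cm)
        assert np.max(np.abs(fast - slow) / np.abs(slow)) < 1e-10

    def test_rooting_invariance(self, rng):
        cm = random_class_model(rng, n_tips=6)
        paln = small_pattern_alignment(cm, 80, rng)
        base = mm.class_site_log_likelihoods(paln, cm)
        for node in range(cm.tree.n_tips, cm.tree.n_nodes):
            cm2 = mm.ClassModel(cm.tree.rerooted(node), cm.gtr, cm.freqs, cm.rhas)
            alt = mm.class_site_log_likelihoods(paln, cm2)
            assert np.allclose(alt, base, atol=1e-9)

    def test_near_zero_branches_give_stationary_likelihood(self):
        # constant column, all branch lengths at the floor: L ~ pi_x
        tree = mm.TreeTopology.from_newick(
            "((a:1e-9,b:1e-9):1e-9,c:1e-9,d:1e-9);")
        freqs = mm.BaseFrequencies(np.array([0.4, 0.3, 0.2, 0.1]))
        cm = mm.ClassModel(tree, mm.GTRParams.jc(), freqs, mm.GammaRHAS.none())
        aln = mm.Alignment.from_records(
            [("a", "AC"), ("b", "AC"), ("c", "AC"), ("d", "AC")])
        paln = compress_patterns(aln)
        logl = mm.class_site_log_likelihoods(paln, cm)
        order = np.argsort(paln.site_to_pattern[:2])  # column A then C
        expect = sorted([math.log(0.4), math.log(0.3)], reverse=True)
        assert sorted(logl.tolist(), reverse=True) == pytest.approx(expect, abs=1e-6)

    def test_gap_columns_have_likelihood_one(self, rng):
        cm = random_class_model(rng, n_tips=4, ncat=2)
        aln = mm.Alignment.from_records(
            [("t0", "N-"), ("t1", "?N"), ("t2", "NN"), ("t3", "--")])
        paln = compress_patterns(aln)
        logl = mm.class_site_log_likelihoods(paln, cm)
        assert np.allclose(logl, 0.0, atol=1e-10)


class TestMixtureFormulas:
    def test_hand_example(self):
        log_L = np.log(np.array([[2e-5, 1e-5]]))
        L = SiteLikelihoodMatrix(log_L=log_L, pattern_weights=np.array([1]))
        w = np.array([0.25, 0.75])
        mix = mm.mixture_site_likelihood(L, w)
        assert mix[0] == pytest.approx(math.log(1.25e-5), abs=1e-12)
        post = mm.posterior_assignment(L, w)
        assert post[0].tolist() == pytest.approx([0.4, 0.6], abs=1e-12)

    def test_single_class_returns_input(self, rng):
        logs = rng.normal(-10, 2, size=(7, 1))
        L = SiteLikelihoodMatrix(log_L=logs, pattern_weights=np.ones(7, int))
        assert np.allclose(mm.mixture_site_likelihood(L, np.array([1.0])),
                           logs[:, 0])

    def test_identical_classes_collapse_for_any_weights(self, rng):
        col = rng.normal(-8, 1, size=12)
        L = SiteLikelihoodMatrix(log_L=np.column_stack([col, col, col]),
                                 pattern_weights=np.ones(12, int))
        for w in ([0.2, 0.3, 0.5], [1 - 2e-6, 1e-6, 1e-6]):
            assert np.allclose(mm.mixture_site_likelihood(L, np.array(w)), col,
                               atol=1e-9)

    def test_total_loglik_weights_patterns(self):
        L = SiteLikelihoodMatrix(log_L=np.array([[math.log(0.5)]]),
                                 pattern_weights=np.array([10]))
        assert mm.total_log_likelihood(L, np.array([1.0])) == \
            pytest.approx(10 * math.log(0.5))

    def test_weight_validation(self):
        L = SiteLikelihoodMatrix(log_L=np.zeros((3, 2)),
                                 pattern_weights=np.ones(3, int))
        with pytest.raises(ValueError):
            mm.mixture_site_likelihood(L, np.array([0.5, 0.25, 0.25]))
        with pytest.raises(ValueError):
            mm.mixture_site_likelihood(L, np.array([1.2, -0.2]))

    def test_posterior_rows_sum_to_one(self, rng):
        logs = rng.normal(-15, 1, size=(40, 4))
        L = SiteLikelihoodMatrix(log_L=logs, pattern_weights=np.ones(40, int))
        w = rng.dirichlet(np.ones(4))
        post = mm.posterior_assignment(L, w)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
        near_one = np.array([1 - 3e-6, 1e-6, 1e-6, 1e-6])
        post2 = mm.posterior_assignment(L, near_one / near_one.sum())
        assert post2[:, 0].min() > 0.99

    def test_expected_class_loglik_brute_force(self, rng):
        logs = rng.normal(-12, 2, size=(9, 3))
        w = np.array([3, 1, 2, 1, 1, 4, 1, 2, 1])
        post = rng.dirichlet(np.ones(3), size=9)
        got = mm.expected_class_log_likelihood(post[:, 1], logs[:, 1], w)
        want = sum(w[i] * post[i, 1] * logs[i, 1] for i in range(9))
        assert got == pytest.approx(want, rel=1e-12)
        assert mm.expected_class_log_likelihood(
            np.zeros(9), logs[:, 0], w) == 0.0


class TestAnalyticGradients:
    def _numeric(self, fn, x0, h=1e-6):
        g = np.zeros_like(x0)
        for k in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += h; xm[k] -= h
            g[k] = (fn(xp) - fn(xm)) / (2 * h)
        return g

    def test_branch_gradient(self, rng):
        cm = random_class_model(rng, n_tips=5)
        paln = small_pattern_alignment(cm, 150, rng)
        vw = paln.weights * rng.uniform(0.1, 1.0, paln.n_patterns)
        val, grad, en = weighted_loglik_and_branch_grad(paln, cm, vw)

        def f(b):
            lengths = cm.tree.lengths.copy()
            lengths[en] = b
            cm2 = mm.ClassModel(cm.tree.with_lengths(lengths), cm.gtr,
                                cm.freqs, cm.rhas)
            return float(vw @ mm.class_site_log_likelihoods(paln, cm2))

        num = self._numeric(f, cm.tree.lengths[en].copy())
        assert np.max(np.abs(grad - num)) < 1e-5 * max(1.0, np.abs(num).max())

    def test_model_parameter_gradients(self, rng):
        cm = random_class_model(rng, n_tips=5)
        paln = small_pattern_alignment(cm, 150, rng)
        vw = paln.weights.astype(float)
        _, g = class_loglik_and_gradients(paln, cm, vw)

        r0 = np.log(cm.gtr.rates[:5])
        def f_gtr(x):
            cm2 = mm.ClassModel(cm.tree, mm.GTRParams(np.append(np.exp(x), 1.0)),
                                cm.freqs, cm.rhas)
            return float(vw @ mm.class_site_log_likelihoods(paln, cm2))
        assert np.allclose(self._numeric(f_gtr, r0), g["gtr"], atol=1e-4)

        f0 = np.log(cm.freqs.pi[:3] / cm.freqs.pi[3])
        def f_freq(x):
            e = np.exp(np.append(x, 0.0))
            cm2 = mm.ClassModel(cm.tree, cm.gtr,
                                mm.BaseFrequencies(e / e.sum()), cm.rhas)
            return float(vw @ mm.class_site_log_likelihoods(paln, cm2))
        assert np.allclose(self._numeric(f_freq, f0), g["freqs"], atol=1e-4)

        a0 = np.array([math.log(cm.rhas.alpha)])
        def f_alpha(x):
            cm2 = mm.ClassModel(cm.tree, cm.gtr, cm.freqs,
                                mm.discretize_gamma(float(np.exp(x[0])), 4))
            return float(vw @ mm.class_site_log_likelihoods(paln, cm2))
        assert self._numeric(f_alpha, a0)[0] == pytest.approx(g["alpha"], abs=1e-4)
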