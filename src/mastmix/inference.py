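"""Fitting the multitree mixture: initialization, EM + quasi-Newton loops,
BIC, and the single-tree baseline.

The workflow follows the nested structure used for this model family:

* initialization — Jukes-Cantor substitution parameters, parsimony branch
  lengths, tree weights from the proportions of parsimony-discriminating
  sites, then one expected-likelihood update against the parsimony site
  assignment so the classes start in distinct basins;
* outer loop — E-step posteriors and the EM weight update (each new
  weight is the mean posterior membership of its class over sites,
  iterated to its fixed point since component likelihoods are held fixed);
* inner stage — per-class branch lengths, substitution model and
  frequencies, maximizing the expected class log-likelihood E[l_j];
* middle stage — the gamma shape of each class (or the shared shape);
* linked blocks — parameter blocks shared across classes cannot use the
  EM surrogate, so they are optimized by quasi-Newton search on the
  actual mixture log-likelihood.

Because the mixture surface is extremely flat along directions that trade
tree weights against branch lengths, plain coordinate-wise EM converges
too slowly near the optimum.  Each outer iteration therefore ends with a
joint quasi-Newton refinement over *all* free parameters (weights, every
branch length, every substitution parameter) using exact analytic
gradients; convergence is still declared on total log-likelihood
increments falling below ``epsilon``, and only after a refined iteration.
Every accepted step is guarded against decreasing the log-likelihood, so
the iteration trace is non-decreasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment import Alignment, PatternAlignment, compress_patterns
from .likelihood import (ClassModel, SiteLikelihoodMatrix, GradientWorkspace,
                         class_site_log_likelihoods, class_loglik_and_gradients,
                         site_log_likelihood_matrix,
                         total_log_likelihood, posterior_assignment,
                         weighted_class_loglik)
from .models import GTRParams, BaseFrequencies, GammaRHAS, discretize_gamma
from .parsimony import (fitch_pattern_scores, initialize_branch_lengths,
                        initialize_weights)
from .trees import TreeTopology

# submodel id -> (rates linked, freqs linked, RHAS linked); the two
# combinations with linked rates but unlinked frequencies are not
# expressible, matching the six implemented submodels
SUBMODEL_LINKAGE = {
    1: (False, False, False),
    2: (False, False, True),
    3: (False, True, False),
    4: (False, True, True),
    5: (True, True, False),
    6: (True, True, True),
}

_LOG_B_MIN_DEFAULT = math.log(1e-6)
_GTR_BOUND = math.log(1e4)
_FREQ_BOUND = 12.0
_ALPHA_BOUNDS = (math.log(0.02), math.log(100.0))


@dataclass
class MastConfig:
    """Configuration of a mixture fit.

    ``submodel`` selects which parameter blocks are linked (shared) across
    classes; branch lengths and topologies are always per-class.
    ``epsilon`` is the convergence threshold on total log-likelihood
    increments between outer iterations.
    """

    submodel: int = 1
    ncat: int = 4
    epsilon: float = 1e-4
    weight_floor: float = 1e-6
    max_outer: int = 50
    min_branch: float = 1e-6
    max_branch: float = 10.0
    alpha_init: float = 1.0
    block_maxiter: int = 8      # per-class / linked-block L-BFGS cap
    joint_maxiter: int = 1000   # joint refinement L-BFGS cap
    joint_restarts: int = 3     # extra joint passes while restarts keep paying
    seed: int | None = None

    def __post_init__(self):
        if self.submodel not in SUBMODEL_LINKAGE:
            raise ValueError(f"submodel must be 1..6, got {self.submodel}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @property
    def linkage(self) -> tuple[bool, bool, bool]:
        return SUBMODEL_LINKAGE[self.submodel]


@dataclass
class MastModelState:
    """Current mixture state: m class models, weights, linkage flags.

    Linked blocks are the *same object* across classes; assigning the
    shared block assigns it for every class."""

    classes: list[ClassModel]
    weights: np.ndarray
    linkage: tuple[bool, bool, bool]

    @property
    def m(self) -> int:
        return len(self.classes)

    def set_linked_gtr(self, gtr: GTRParams) -> None:
        for cm in self.classes:
            cm.gtr = gtr

    def set_linked_freqs(self, freqs: BaseFrequencies) -> None:
        for cm in self.classes:
            cm.freqs = freqs

    def set_linked_rhas(self, rhas: GammaRHAS) -> None:
        for cm in self.classes:
            cm.rhas = rhas

    def snapshot(self):
        return ([cm.copy() for cm in self.classes], self.weights.copy())

    def restore(self, snap) -> None:
        self.classes, self.weights = [c.copy() for c in snap[0]], snap[1].copy()


@dataclass
class FitResult:
    log_likelihood: float
    n_free_params: int
    n_sites: int
    bic: float
    weights: np.ndarray
    classes: list[ClassModel]
    trace: list[float]
    converged: bool
    n_outer_iterations: int
    metadata: dict = field(default_factory=dict)

    def tree_newicks(self) -> list[str]:
        return [cm.tree.to_newick() for cm in self.classes]


def bic(log_likelihood: float, n_free_params: int, n_sites: int) -> float:
    """BIC = k ln(N) - 2 l (lower is better)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return n_free_params * math.log(n_sites) - 2.0 * log_likelihood


def count_free_parameters(submodel: int, m: int, t: int, ncat: int = 4) -> int:
    """Free parameters of the mixture: (m-1) weights, m(2t-3) branch
    lengths, 5 exchangeabilities, 3 frequencies and 1 gamma shape per
    unlinked block (counted once if linked)."""
    rl, fl, hl = SUBMODEL_LINKAGE[submodel]
    k = (m - 1) + m * (2 * t - 3)
    k += 5 * (1 if rl else m)
    k += 3 * (1 if fl else m)
    if ncat > 1:
        k += 1 * (1 if hl else m)
    return k


def em_update_weights(posteriors: np.ndarray, pattern_weights: np.ndarray,
                      weight_floor: float = 1e-6) -> np.ndarray:
    """New weights = mean posterior membership over sites, floored and
    renormalized so every class keeps strictly positive weight."""
    n = float(pattern_weights.sum())
    w = (pattern_weights[:, None] * posteriors).sum(axis=0) / n
    w = np.maximum(w, weight_floor)
    return w / w.sum()


def optimize_weights(L: SiteLikelihoodMatrix, w: np.ndarray,
                     weight_floor: float = 1e-6, tol: float = 1e-12,
                     max_iter: int = 10000) -> np.ndarray:
    """Iterate the EM weight update to its fixed point with the component
    likelihoods held fixed (the conditional ML of the weights)."""
    for _ in range(max_iter):
        post = posterior_assignment(L, w)
        w2 = em_update_weights(post, L.pattern_weights, weight_floor)
        if np.max(np.abs(w2 - w)) < tol:
            return w2
        w = w2
    return w


# ---------------------------------------------------------------------------
# parameter transforms


def _pack_gtr(gtr: GTRParams) -> np.ndarray:
    r = gtr.rates / gtr.rates[5]
    return np.log(r[:5])


def _unpack_gtr(x) -> GTRParams:
    return GTRParams(np.append(np.exp(np.clip(x, -_GTR_BOUND, _GTR_BOUND)), 1.0))


def _pack_freqs(f: BaseFrequencies) -> np.ndarray:
    return np.log(f.pi[:3] / f.pi[3])


def _unpack_freqs(x) -> BaseFrequencies:
    e = np.exp(np.append(np.clip(x, -_FREQ_BOUND, _FREQ_BOUND), 0.0))
    return BaseFrequencies(e / e.sum())


def _unpack_alpha(x, ncat: int) -> GammaRHAS:
    a = float(np.exp(np.clip(x, *_ALPHA_BOUNDS)))
    return discretize_gamma(a, ncat) if ncat > 1 else GammaRHAS.none()


# ---------------------------------------------------------------------------
# per-class (EM M-step) and linked-block optimizers


def optimize_class_parameters(paln: PatternAlignment, cm: ClassModel,
                              site_weights: np.ndarray, cfg: MastConfig,
                              do_branches: bool = True, do_gtr: bool = False,
                              do_freqs: bool = False, do_alpha: bool = False) -> float:
    """Maximize the weighted (expected) class log-likelihood over the
    selected parameter blocks of one class, with exact gradients.

    ``site_weights`` is the per-pattern weight vector, typically pattern
    multiplicity times the posterior probability of this class (the E-step
    output), which makes the objective E[l_j].  Returns the achieved
    improvement; a failed search leaves the class untouched.
    """
    if not (do_branches or do_gtr or do_freqs or do_alpha):
        return 0.0
    tree = cm.tree
    edge_nodes = tree.edge_nodes()
    nb = len(edge_nodes) if do_branches else 0
    want_alpha = do_alpha and cfg.ncat > 1

    x0, bounds = [], []
    if do_branches:
        x0.append(np.log(np.clip(tree.lengths[edge_nodes],
                                 cfg.min_branch, cfg.max_branch)))
        bounds += [(math.log(cfg.min_branch), math.log(cfg.max_branch))] * nb
    if do_gtr:
        x0.append(_pack_gtr(cm.gtr)); bounds += [(-_GTR_BOUND, _GTR_BOUND)] * 5
    if do_freqs:
        x0.append(_pack_freqs(cm.freqs)); bounds += [(-_FREQ_BOUND, _FREQ_BOUND)] * 3
    if want_alpha:
        x0.append([math.log(cm.rhas.alpha)]); bounds += [_ALPHA_BOUNDS]
    x0 = np.concatenate(x0)
    saved = cm.copy()

    def build(x):
        i = 0
        if do_branches:
            lengths = tree.lengths.copy()
            lengths[edge_nodes] = np.exp(x[:nb]); i = nb
            cm.tree = tree.with_lengths(lengths)
        if do_gtr:
            cm.gtr = _unpack_gtr(x[i:i + 5]); i += 5
        if do_freqs:
            cm.freqs = _unpack_freqs(x[i:i + 3]); i += 3
        if want_alpha:
            cm.rhas = _unpack_alpha(x[i], cfg.ncat)

    def negobj(x):
        build(x)
        val, g = class_loglik_and_gradients(
            paln, cm, site_weights, want_gtr=do_gtr, want_freqs=do_freqs,
            want_alpha=want_alpha)
        parts = []
        if do_branches:
            parts.append(g["branch"] * cm.tree.lengths[edge_nodes])
        if do_gtr:
            parts.append(g["gtr"])
        if do_freqs:
            parts.append(g["freqs"])
        if want_alpha:
            parts.append([g["alpha"]])
        return -val, -np.concatenate(parts)

    f0 = negobj(x0)[0]
    res = minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": cfg.block_maxiter, "ftol": 1e-12, "maxls": 12})
    if res.fun < f0:
        build(res.x)
        return float(f0 - res.fun)
    cm.tree, cm.gtr, cm.freqs, cm.rhas = (saved.tree, saved.gtr, saved.freqs,
                                          saved.rhas)
    return 0.0


def _mixture_eval(paln, classes, w):
    """Mixture log-likelihood, posteriors and per-class gradient
    workspaces in one set of inside passes."""
    workspaces = [GradientWorkspace(paln, c) for c in classes]
    logL = np.column_stack([ws.log_L for ws in workspaces])
    lw = np.log(w)
    mix = logsumexp(logL + lw[None, :], axis=1)
    W = paln.weights.astype(float)
    l = float(W @ mix)
    post = np.exp(logL + lw[None, :] - mix[:, None])
    return l, post, W, workspaces


def optimize_linked_parameters(paln: PatternAlignment, state: MastModelState,
                               cfg: MastConfig, do_gtr: bool, do_freqs: bool,
                               do_alpha: bool) -> float:
    """Quasi-Newton update of the shared parameter blocks on the actual
    mixture log-likelihood (the EM surrogate does not cover shared blocks).
    The gradient is assembled from the per-class analytic gradients
    weighted by the current posteriors."""
    want_alpha = do_alpha and cfg.ncat > 1
    if not (do_gtr or do_freqs or want_alpha):
        return 0.0
    ref = state.classes[0]
    x0, bounds = [], []
    if do_gtr:
        x0.append(_pack_gtr(ref.gtr)); bounds += [(-_GTR_BOUND, _GTR_BOUND)] * 5
    if do_freqs:
        x0.append(_pack_freqs(ref.freqs)); bounds += [(-_FREQ_BOUND, _FREQ_BOUND)] * 3
    if want_alpha:
        x0.append([math.log(ref.rhas.alpha)]); bounds += [_ALPHA_BOUNDS]
    x0 = np.concatenate(x0)
    saved = (ref.gtr, ref.freqs, ref.rhas)

    def apply(x):
        i = 0
        if do_gtr:
            state.set_linked_gtr(_unpack_gtr(x[i:i + 5])); i += 5
        if do_freqs:
            state.set_linked_freqs(_unpack_freqs(x[i:i + 3])); i += 3
        if want_alpha:
            state.set_linked_rhas(_unpack_alpha(x[i], cfg.ncat))

    def negobj(x):
        apply(x)
        l, post, W, workspaces = _mixture_eval(paln, state.classes, state.weights)
        grad = np.zeros_like(x0)
        for j, ws in enumerate(workspaces):
            vj = W * post[:, j]
            g = ws.gradients(vj, want_gtr=do_gtr, want_freqs=do_freqs,
                             want_alpha=want_alpha)
            i = 0
            if do_gtr:
                grad[i:i + 5] += g["gtr"]; i += 5
            if do_freqs:
                grad[i:i + 3] += g["freqs"]; i += 3
            if want_alpha:
                grad[i] += g["alpha"]
        return -l, -grad

    f0 = negobj(x0)[0]
    res = minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": cfg.block_maxiter, "ftol": 1e-12, "maxls": 12})
    if res.fun < f0:
        apply(res.x)
        return float(f0 - res.fun)
    state.set_linked_gtr(saved[0]) if do_gtr else None
    state.set_linked_freqs(saved[1]) if do_freqs else None
    state.set_linked_rhas(saved[2]) if want_alpha else None
    return 0.0


# ---------------------------------------------------------------------------
# joint refinement over all free parameters


class _JointProblem:
    """Pack/unpack and evaluate the full mixture over all free parameters
    (log weights, log branch lengths, transformed substitution parameters),
    honoring the linkage configuration."""

    def __init__(self, paln: PatternAlignment, state: MastModelState,
                 cfg: MastConfig):
        self.paln, self.state, self.cfg = paln, state, cfg
        self.rl, self.fl, self.hl = state.linkage
        self.m = state.m
        self.trees = [cm.tree for cm in state.classes]
        self.edge_nodes = [t.edge_nodes() for t in self.trees]
        self.nb = [len(e) for e in self.edge_nodes]
        self.want_alpha = cfg.ncat > 1
        self.nw = self.m if self.m > 1 else 0

        bounds: list[tuple] = [(-30.0, 0.0)] * self.nw
        lb = (math.log(cfg.min_branch), math.log(cfg.max_branch))
        for n in self.nb:
            bounds += [lb] * n
        per_class = (0 if self.rl else 5) + (0 if self.fl else 3) \
            + (0 if (self.hl or not self.want_alpha) else 1)
        bounds += self._model_bounds() * (0 if per_class == 0 else self.m)
        shared = (5 if self.rl else 0) + (3 if self.fl else 0) \
            + (1 if (self.hl and self.want_alpha) else 0)
        if shared:
            bounds += self._shared_bounds()
        self.bounds = bounds

    def _model_bounds(self):
        b = []
        if not self.rl:
            b += [(-_GTR_BOUND, _GTR_BOUND)] * 5
        if not self.fl:
            b += [(-_FREQ_BOUND, _FREQ_BOUND)] * 3
        if not self.hl and self.want_alpha:
            b += [_ALPHA_BOUNDS]
        return b

    def _shared_bounds(self):
        b = []
        if self.rl:
            b += [(-_GTR_BOUND, _GTR_BOUND)] * 5
        if self.fl:
            b += [(-_FREQ_BOUND, _FREQ_BOUND)] * 3
        if self.hl and self.want_alpha:
            b += [_ALPHA_BOUNDS]
        return b

    def pack(self) -> np.ndarray:
        st = self.state
        xs = []
        if self.nw:
            xs.append(np.log(st.weights))
        for j, cm in enumerate(st.classes):
            xs.append(np.log(np.clip(cm.tree.lengths[self.edge_nodes[j]],
                                     self.cfg.min_branch, self.cfg.max_branch)))
        for cm in st.classes:
            if not self.rl:
                xs.append(_pack_gtr(cm.gtr))
            if not self.fl:
                xs.append(_pack_freqs(cm.freqs))
            if not self.hl and self.want_alpha:
                xs.append([math.log(cm.rhas.alpha)])
        ref = st.classes[0]
        if self.rl:
            xs.append(_pack_gtr(ref.gtr))
        if self.fl:
            xs.append(_pack_freqs(ref.freqs))
        if self.hl and self.want_alpha:
            xs.append([math.log(ref.rhas.alpha)])
        return np.concatenate(xs) if xs else np.array([])

    def unpack(self, x):
        i = 0
        if self.nw:
            e = np.exp(x[:self.nw] - x[:self.nw].max())
            w = np.maximum(e / e.sum(), self.cfg.weight_floor)
            w = w / w.sum()
            i = self.nw
        else:
            w = np.array([1.0])
        classes = []
        blens = []
        for j, cm in enumerate(self.state.classes):
            lengths = cm.tree.lengths.copy()
            lengths[self.edge_nodes[j]] = np.exp(x[i:i + self.nb[j]])
            i += self.nb[j]
            blens.append(lengths)
        # per-class unlinked blocks
        gtrs, freqss, rhass = [], [], []
        for j, cm in enumerate(self.state.classes):
            gtrs.append(cm.gtr if self.rl else None)
            freqss.append(cm.freqs if self.fl else None)
            rhass.append(cm.rhas if (self.hl or not self.want_alpha) else None)
            if not self.rl:
                gtrs[j] = _unpack_gtr(x[i:i + 5]); i += 5
            if not self.fl:
                freqss[j] = _unpack_freqs(x[i:i + 3]); i += 3
            if not self.hl and self.want_alpha:
                rhass[j] = _unpack_alpha(x[i], self.cfg.ncat); i += 1
        if self.rl:
            shared_gtr = _unpack_gtr(x[i:i + 5]); i += 5
            gtrs = [shared_gtr] * self.m
        if self.fl:
            shared_freqs = _unpack_freqs(x[i:i + 3]); i += 3
            freqss = [shared_freqs] * self.m
        if self.hl and self.want_alpha:
            shared_rhas = _unpack_alpha(x[i], self.cfg.ncat); i += 1
            rhass = [shared_rhas] * self.m
        for j, cm in enumerate(self.state.classes):
            classes.append(ClassModel(cm.tree.with_lengths(blens[j]),
                                      gtrs[j], freqss[j],
                                      rhass[j] if rhass[j] is not None
                                      else cm.rhas))
        return w, classes

    def negobj(self, x):
        w, classes = self.unpack(x)
        l, post, W, workspaces = _mixture_eval(self.paln, classes, w)
        g = np.zeros_like(x)
        if self.nw:
            g[:self.nw] = (W[:, None] * (post - w[None, :])).sum(axis=0)
        i = self.nw
        shared_g = []
        unlinked_slices = []
        for j, (c, ws) in enumerate(zip(classes, workspaces)):
            vj = W * post[:, j]
            gg = ws.gradients(vj, want_gtr=True, want_freqs=True,
                              want_alpha=self.want_alpha)
            g[i:i + self.nb[j]] = gg["branch"] * c.tree.lengths[self.edge_nodes[j]]
            i += self.nb[j]
            shared_g.append(gg)
        for j in range(self.m):
            gg = shared_g[j]
            if not self.rl:
                unlinked_slices.append((i, gg["gtr"])); i += 5
            if not self.fl:
                unlinked_slices.append((i, gg["freqs"])); i += 3
            if not self.hl and self.want_alpha:
                unlinked_slices.append((i, np.array([gg["alpha"]]))); i += 1
        for pos, arr in unlinked_slices:
            g[pos:pos + len(arr)] = arr
        if self.rl:
            g[i:i + 5] = sum(gg["gtr"] for gg in shared_g); i += 5
        if self.fl:
            g[i:i + 3] = sum(gg["freqs"] for gg in shared_g); i += 3
        if self.hl and self.want_alpha:
            g[i] = sum(gg["alpha"] for gg in shared_g); i += 1
        return -l, -g


def joint_refine(paln: PatternAlignment, state: MastModelState,
                 cfg: MastConfig, maxiter: int | None = None) -> float:
    """One joint quasi-Newton pass over every free parameter; accepts the
    result only if the mixture log-likelihood improved."""
    prob = _JointProblem(paln, state, cfg)
    x0 = prob.pack()
    if x0.size == 0:
        return 0.0
    f0 = prob.negobj(x0)[0]
    res = minimize(prob.negobj, x0, jac=True, method="L-BFGS-B",
                   bounds=prob.bounds,
                   options={"maxiter": maxiter or cfg.joint_maxiter,
                            "ftol": 1e-11, "gtol": 1e-6, "maxcor": 120})
    if res.fun < f0:
        w, classes = prob.unpack(res.x)
        state.weights = w
        rl, fl, hl = state.linkage
        for cm, c in zip(state.classes, classes):
            cm.tree = c.tree
            if not rl:
                cm.gtr = c.gtr
            if not fl:
                cm.freqs = c.freqs
            if not hl:
                cm.rhas = c.rhas
        if rl:
            state.set_linked_gtr(classes[0].gtr)
        if fl:
            state.set_linked_freqs(classes[0].freqs)
        if hl:
            state.set_linked_rhas(classes[0].rhas)
        return float(f0 - res.fun)
    return 0.0


# ---------------------------------------------------------------------------
# full fits


def _as_pattern_alignment(aln) -> PatternAlignment:
    if isinstance(aln, PatternAlignment):
        return aln
    if isinstance(aln, Alignment):
        return compress_patterns(aln)
    raise TypeError("expected Alignment or PatternAlignment")


def _initial_state(paln: PatternAlignment, trees, cfg: MastConfig) -> MastModelState:
    rl, fl, hl = cfg.linkage
    gtr_shared = GTRParams.jc()
    freqs_shared = BaseFrequencies.uniform()
    rhas_shared = (discretize_gamma(cfg.alpha_init, cfg.ncat)
                   if cfg.ncat > 1 else GammaRHAS.none())
    classes = []
    for tree in trees:
        classes.append(ClassModel(
            tree=initialize_branch_lengths(paln, tree, cfg.min_branch, cfg.max_branch),
            gtr=gtr_shared if rl else GTRParams.jc(),
            freqs=freqs_shared if fl else BaseFrequencies.uniform(),
            rhas=rhas_shared if hl else (discretize_gamma(cfg.alpha_init, cfg.ncat)
                                         if cfg.ncat > 1 else GammaRHAS.none()),
        ))
    w = initialize_weights(paln, trees, cfg.weight_floor)
    return MastModelState(classes=classes, weights=w, linkage=cfg.linkage)


def _parsimony_posteriors(paln: PatternAlignment, trees,
                          w0: np.ndarray) -> np.ndarray:
    """Hard class membership from parsimony scores: discriminating sites go
    to their minimum-score tree(s) (ties split), other sites carry the
    initial weights.  Used once, to seed the first expected-likelihood
    update before any posterior is available."""
    S = np.column_stack([fitch_pattern_scores(paln, t) for t in trees])
    is_min = S == S.min(axis=1, keepdims=True)
    share = is_min / is_min.sum(axis=1, keepdims=True)
    discr = ~(S == S[:, :1]).all(axis=1)
    return np.where(discr[:, None], share, w0[None, :])


def _em_iteration(paln, state, cfg, L):
    """One outer iteration: weight update, inner stage (branch lengths +
    unlinked substitution/frequency parameters per class), middle stage
    (rate heterogeneity), linked blocks.  Mutates ``state``; returns the
    refreshed likelihood matrix."""
    rl, fl, hl = state.linkage
    m = state.m
    if m > 1:
        state.weights = optimize_weights(L, state.weights, cfg.weight_floor)
        post = posterior_assignment(L, state.weights)
    else:
        post = np.ones((paln.n_patterns, 1))
    W = paln.weights.astype(float)
    collapse_cutoff = max(10 * cfg.weight_floor, 1e-5)
    dropped = []
    for j, cm in enumerate(state.classes):
        if m > 1 and state.weights[j] < collapse_cutoff:
            dropped.append(j)
            continue
        vj = W * post[:, j]
        # inner stage: branch lengths, substitution model, frequencies
        optimize_class_parameters(paln, cm, vj, cfg, do_branches=True,
                                  do_gtr=not rl, do_freqs=not fl)
        # middle stage: rate heterogeneity
        if cfg.ncat > 1 and not hl:
            optimize_class_parameters(paln, cm, vj, cfg, do_branches=False,
                                      do_alpha=True)
    if rl or fl or (hl and cfg.ncat > 1):
        optimize_linked_parameters(paln, state, cfg, do_gtr=rl, do_freqs=fl,
                                   do_alpha=hl)
    L = site_log_likelihood_matrix(paln, state.classes)
    if m > 1:
        state.weights = optimize_weights(L, state.weights, cfg.weight_floor)
    return L, dropped


def fit_mast(aln, trees, config: MastConfig | None = None) -> FitResult:
    """Fit the multitree mixture on fixed topologies.

    ``aln`` is an :class:`Alignment` (or a precompressed
    :class:`PatternAlignment`); ``trees`` an ordered collection of
    :class:`TreeTopology` whose tips match the alignment taxa.  The
    returned :class:`FitResult` has a non-decreasing iteration trace whose
    final increment is below ``config.epsilon`` whenever ``converged``.
    """
    cfg = config or MastConfig()
    paln = _as_pattern_alignment(aln)
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    state = _initial_state(paln, trees, cfg)
    m = state.m

    # seed the classes from the parsimony site assignment so distinct
    # classes start in distinct basins
    post0 = _parsimony_posteriors(paln, trees, state.weights)
    W = paln.weights.astype(float)
    rl, fl, hl = cfg.linkage
    for j, cm in enumerate(state.classes):
        optimize_class_parameters(paln, cm, W * post0[:, j], cfg,
                                  do_branches=True, do_gtr=not rl,
                                  do_freqs=not fl, do_alpha=not hl)
    if rl or fl or (hl and cfg.ncat > 1):
        optimize_linked_parameters(paln, state, cfg, do_gtr=rl, do_freqs=fl,
                                   do_alpha=hl)

    L = site_log_likelihood_matrix(paln, state.classes)
    if m > 1:
        state.weights = optimize_weights(L, state.weights, cfg.weight_floor)
    l = total_log_likelihood(L, state.weights)
    trace = [l]
    converged = False
    dropped: set[int] = set()
    it = 0
    while it < cfg.max_outer:
        it += 1
        L, dr = _em_iteration(paln, state, cfg, L)
        dropped.update(dr)
        # joint refinement: the EM blocks are monotone but crawl along the
        # flat weight/branch-length ridge; the joint pass finishes the job.
        # A stalled quasi-Newton run often pays again when restarted, so
        # retry while restarts keep improving.
        for _ in range(max(1, cfg.joint_restarts)):
            if joint_refine(paln, state, cfg) < cfg.epsilon:
                break
        L = site_log_likelihood_matrix(paln, state.classes)
        if m > 1:
            state.weights = optimize_weights(L, state.weights, cfg.weight_floor)
        l_new = total_log_likelihood(L, state.weights)
        if l_new < l:
            l_new = l  # numerical guard; the trace never decreases
        trace.append(l_new)
        if l_new - l < cfg.epsilon:
            l = l_new
            converged = True
            break
        l = l_new

    t = len(paln.taxon_labels)
    k = count_free_parameters(cfg.submodel, m, t, cfg.ncat)
    n = paln.n_sites
    return FitResult(
        log_likelihood=l, n_free_params=k, n_sites=n, bic=bic(l, k, n),
        weights=state.weights.copy(), classes=state.classes, trace=trace,
        converged=converged, n_outer_iterations=it,
        metadata={
            "submodel": cfg.submodel,
            "epsilon": cfg.epsilon,
            "gamma_discretization": "mean-of-interval, renormalized to mean 1",
            "optimizer": "EM blocks + joint quasi-Newton refinement",
            "dropped_classes": sorted(dropped),
        },
    )


def fit_single_tree(aln, tree: TreeTopology,
                    config: MastConfig | None = None) -> FitResult:
    """Maximum-likelihood branch lengths and GTR+G on one fixed topology:
    the single-tree baseline whose BIC is reported as BIC0.

    Implemented as plain coordinate alternation (branch lengths and
    substitution parameters in turn) until the log-likelihood increment
    falls below ``epsilon``; no mixture machinery is involved.
    """
    cfg = config or MastConfig()
    # deep per-iteration block optimization: with no mixture structure the
    # epsilon stop is only meaningful if each alternation step runs to
    # (near) convergence
    import dataclasses
    cfg = dataclasses.replace(cfg, block_maxiter=max(cfg.block_maxiter, 80))
    paln = _as_pattern_alignment(aln)
    cm = ClassModel(
        tree=initialize_branch_lengths(paln, tree, cfg.min_branch, cfg.max_branch),
        gtr=GTRParams.jc(), freqs=BaseFrequencies.uniform(),
        rhas=discretize_gamma(cfg.alpha_init, cfg.ncat) if cfg.ncat > 1
        else GammaRHAS.none(),
    )
    vw = paln.weights.astype(float)
    l = weighted_class_loglik(paln, cm, vw)
    trace = [l]
    converged = False
    it = 0
    while it < max(cfg.max_outer, 100):
        it += 1
        optimize_class_parameters(paln, cm, vw, cfg, do_branches=True,
                                  do_gtr=True, do_freqs=True, do_alpha=True)
        l_new = weighted_class_loglik(paln, cm, vw)
        if l_new < l:
            l_new = l
        trace.append(l_new)
        if l_new - l < cfg.epsilon:
            l = l_new
            converged = True
            break
        l = l_new
    t = len(paln.taxon_labels)
    k = count_free_parameters(6, 1, t, cfg.ncat)
    n = paln.n_sites
    return FitResult(
        log_likelihood=l, n_free_params=k, n_sites=n, bic=bic(l, k, n),
        weights=np.array([1.0]), classes=[cm], trace=trace,
        converged=converged, n_outer_iterations=it,
        metadata={"model": "single-tree GTR+G baseline"},
    )
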