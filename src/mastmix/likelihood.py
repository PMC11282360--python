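"""Per-site likelihoods by Felsenstein pruning, and the mixture likelihood.

The likelihood of site ``i`` under the multitree mixture is

    L_i = sum_j w_j L_ij(T_j, lambda_j, R_j, H_j, F_j),

where ``L_ij`` is the ordinary pruning likelihood of the site on class
``j``'s tree, averaged over the discrete-gamma rate categories.  All
per-site work is done on compressed site patterns; underflow is handled by
per-node scaling vectors accumulated in log space, so pattern
log-likelihoods stay finite for any usable branch lengths.

Besides the plain likelihood, this module computes outside ("down")
conditional likelihoods, which give the exact gradient of the weighted
log-likelihood with respect to every branch length in two extra passes.
That gradient is what makes branch-length optimization affordable inside
the EM loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import PatternAlignment
from .models import GTRParams, BaseFrequencies, GammaRHAS, build_rate_matrix
from .trees import TreeTopology


@dataclass
class ClassModel:
    """One mixture class: a topology with branch lengths plus its
    substitution model, base frequencies and rate-heterogeneity model."""

    tree: TreeTopology
    gtr: GTRParams
    freqs: BaseFrequencies
    rhas: GammaRHAS

    def copy(self) -> "ClassModel":
        return ClassModel(self.tree.copy(), self.gtr.copy(),
                          self.freqs.copy(), self.rhas.copy())


@dataclass
class SiteLikelihoodMatrix:
    """Per-pattern log-likelihoods for every mixture class (patterns x m)."""

    log_L: np.ndarray
    pattern_weights: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.log_L.shape[1])


def _tip_partials(paln: PatternAlignment) -> np.ndarray:
    cached = getattr(paln, "_tip_partials_cache", None)
    if cached is None:
        cached = paln.tip_partials()
        paln._tip_partials_cache = cached  # type: ignore[attr-defined]
    return cached


class _Engine:
    """Pruning workspace for one (pattern alignment, class model) pair."""

    def __init__(self, paln: PatternAlignment, cm: ClassModel):
        tree = cm.tree
        self.tree = tree
        self.paln = paln
        taxon_row = {lab: i for i, lab in enumerate(paln.taxon_labels)}
        try:
            self.tip_rows = np.array([taxon_row[lab] for lab in tree.tip_labels])
        except KeyError as e:
            raise ValueError(f"tree tip {e} not present in alignment") from e
        if len(tree.tip_labels) != len(paln.taxon_labels):
            raise ValueError("tree tips do not exactly match alignment taxa")
        self.post = tree.postorder()
        self.Qm = build_rate_matrix(cm.gtr, cm.freqs)
        self.rates = cm.rhas.category_rates
        self.ncat = cm.rhas.ncat
        self.pi = cm.freqs.pi
        lengths = np.where(np.isnan(tree.lengths), 0.0, tree.lengths)
        # (ncat, n_nodes, 4, 4): transition matrix above each node per category
        self.P = self.Qm.transition_batch(np.outer(self.rates, lengths))
        self.tipp = _tip_partials(paln)
        internals = [v for v in self.post if v >= tree.n_tips]
        # rescaling every few internal nodes is enough to keep float64
        # partials well away from underflow on trees of this size
        self.scale_at = {v for i, v in enumerate(internals) if i % 4 == 3}

    def upward(self):
        """Postorder partials; returns (partials, logscale) keyed by node.

        partials[v]: (ncat, P, 4); logscale[v]: (ncat, P) cumulative."""
        tree, P = self.tree, self.P
        np_, nc = self.paln.n_patterns, self.ncat
        partials: list[np.ndarray | None] = [None] * tree.n_nodes
        logscale: list[np.ndarray | None] = [None] * tree.n_nodes
        for v in self.post:
            if v < tree.n_tips:
                tp = self.tipp[self.tip_rows[v]]  # (P, 4)
                partials[v] = np.broadcast_to(tp, (nc, np_, 4))
                logscale[v] = np.zeros((nc, np_))
                continue
            acc = np.ones((nc, np_, 4))
            sc = np.zeros((nc, np_))
            for c in tree.children[v]:
                # sum_t P[c_above][s,t] * partial_c[t]
                acc = acc * np.matmul(partials[c], np.swapaxes(P[:, c], 1, 2))
                sc = sc + logscale[c]
                partials[c] = None  # conserved only by callers that ask
            if v in self.scale_at:
                m = acc.max(axis=2)
                safe = m > 0
                acc = np.where(safe[..., None],
                               acc / np.where(safe, m, 1.0)[..., None], 0.0)
                sc = sc + np.where(safe, np.log(np.where(safe, m, 1.0)), -np.inf)
            partials[v] = acc
            logscale[v] = sc
        return partials, logscale

    def upward_full(self):
        """Like :meth:`upward` but keeps every node's partial (for gradients)."""
        tree, P = self.tree, self.P
        np_, nc = self.paln.n_patterns, self.ncat
        partials: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore
        logscale: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore
        for v in self.post:
            if v < tree.n_tips:
                partials[v] = np.broadcast_to(
                    self.tipp[self.tip_rows[v]], (nc, np_, 4))
                logscale[v] = np.zeros((nc, np_))
                continue
            acc = np.ones((nc, np_, 4))
            sc = np.zeros((nc, np_))
            for c in tree.children[v]:
                acc = acc * np.matmul(partials[c], np.swapaxes(P[:, c], 1, 2))
                sc = sc + logscale[c]
            if v in self.scale_at:
                m = acc.max(axis=2)
                safe = m > 0
                acc = np.where(safe[..., None],
                               acc / np.where(safe, m, 1.0)[..., None], 0.0)
                sc = sc + np.where(safe, np.log(np.where(safe, m, 1.0)), -np.inf)
            partials[v] = acc
            logscale[v] = sc
        return partials, logscale

    def pattern_log_likelihoods(self):
        partials, logscale = self.upward()
        root = self.tree.root
        site_l = partials[root] @ self.pi  # (ncat, P)
        with np.errstate(divide="ignore"):
            logl = np.log(site_l) + logscale[root]
        return logsumexp(logl, axis=0, b=1.0 / self.ncat)

    def downward(self, partials, logscale):
        """Outside partials F[v]: likelihood of everything outside subtree(v)
        conditional on the state at v's parent, root prior included."""
        tree, P = self.tree, self.P
        np_, nc = self.paln.n_patterns, self.ncat
        F: list[np.ndarray | None] = [None] * tree.n_nodes
        Fscale: list[np.ndarray | None] = [None] * tree.n_nodes
        order = [v for v in reversed(self.post)]  # preorder
        for u in order:
            if u < tree.n_tips:
                continue
            if u == tree.root:
                O_u = np.broadcast_to(self.pi, (nc, np_, 4))
                O_sc = np.zeros((nc, np_))
            else:
                # state distribution at u itself, from F[u] through the edge above u
                O_u = np.matmul(F[u], P[:, u])
                O_sc = Fscale[u]
            kids = tree.children[u]
            contrib = [np.matmul(partials[c], np.swapaxes(P[:, c], 1, 2)) for c in kids]
            for i, v in enumerate(kids):
                acc = O_u
                sc = O_sc
                for jj, w in enumerate(kids):
                    if w == v:
                        continue
                    acc = acc * contrib[jj]
                    sc = sc + logscale[w]
                if v in self.scale_at:
                    m = acc.max(axis=2)
                    safe = m > 0
                    acc = np.where(safe[..., None],
                                   acc / np.where(safe, m, 1.0)[..., None], 0.0)
                    sc = sc + np.where(safe, np.log(np.where(safe, m, 1.0)),
                                       -np.inf)
                F[v] = acc
                Fscale[v] = sc
        return F, Fscale


def class_site_log_likelihoods(paln: PatternAlignment, cm: ClassModel) -> np.ndarray:
    """Per-pattern log-likelihood of one mixture class (gamma-averaged)."""
    return _Engine(paln, cm).pattern_log_likelihoods()


def site_log_likelihood_matrix(paln: PatternAlignment, classes) -> SiteLikelihoodMatrix:
    log_L = np.column_stack([class_site_log_likelihoods(paln, cm) for cm in classes])
    return SiteLikelihoodMatrix(log_L=log_L, pattern_weights=paln.weights)


def mixture_site_likelihood(L: SiteLikelihoodMatrix, w: np.ndarray) -> np.ndarray:
    """log L_i = log sum_j w_j L_ij, per pattern, by log-sum-exp."""
    w = np.asarray(w, dtype=float)
    if w.shape != (L.n_classes,):
        raise ValueError(f"weight vector length {w.shape} != class count {L.n_classes}")
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be strictly positive and sum to 1")
    return logsumexp(L.log_L + np.log(w)[None, :], axis=1)


def total_log_likelihood(L: SiteLikelihoodMatrix, w: np.ndarray) -> float:
    """Full log-likelihood over all sites (pattern-weighted sum)."""
    return float(np.dot(L.pattern_weights, mixture_site_likelihood(L, w)))


def posterior_assignment(L: SiteLikelihoodMatrix, w: np.ndarray) -> np.ndarray:
    """p_ij = w_j L_ij / sum_k w_k L_ik, rows summing to 1 (patterns x m)."""
    logmix = mixture_site_likelihood(L, w)
    return np.exp(L.log_L + np.log(np.asarray(w))[None, :] - logmix[:, None])


def expected_class_log_likelihood(posterior_j: np.ndarray,
                                  class_log_L: np.ndarray,
                                  pattern_weights: np.ndarray) -> float:
    """E[l_j] = sum_i p_ij log L_ij, summed over sites via pattern weights."""
    return float(np.dot(pattern_weights * posterior_j, class_log_L))


def weighted_class_loglik(paln: PatternAlignment, cm: ClassModel,
                          site_weights: np.ndarray) -> float:
    """sum_p v_p log L_p for one class; v_p already includes pattern counts."""
    return float(np.dot(site_weights, class_site_log_likelihoods(paln, cm)))


def _phi_matrix(eigvals: np.ndarray, s) -> np.ndarray:
    """Divided-difference kernel of the matrix exponential: Phi_ij =
    s * (e^{s li} - e^{s lj}) / (s li - s lj), with the confluent limit on
    the diagonal.  Used for directional derivatives of P = exp(Q s);
    ``s`` may be an array of scaled branch lengths (one per category)."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    x = s[:, None] * eigvals[None, :]          # (k, 4)
    ex = np.exp(x)
    dx = x[:, :, None] - x[:, None, :]
    small = np.abs(dx) < 1e-10
    dxs = np.where(small, 1.0, dx)
    phi = np.where(small,
                   np.exp(0.5 * (x[:, :, None] + x[:, None, :])),
                   (ex[:, :, None] - ex[:, None, :]) / dxs)
    return s[:, None, None] * phi


def _dQ_matrices(gtr: GTRParams, freqs: BaseFrequencies, h: float = 1e-6):
    """Derivatives of the normalized rate matrix with respect to the free
    parameters in transformed coordinates (log exchangeabilities 0..4 and
    frequency log-ratios 0..2), by central differences on the cheap 4x4
    construction."""
    from .models import normalized_q
    out = []
    r0 = np.log(gtr.rates[:5])
    for k in range(5):
        rp, rm = r0.copy(), r0.copy()
        rp[k] += h; rm[k] -= h
        Qp = normalized_q(GTRParams(np.append(np.exp(rp), 1.0)), freqs)
        Qm = normalized_q(GTRParams(np.append(np.exp(rm), 1.0)), freqs)
        out.append((Qp - Qm) / (2 * h))
    f0 = np.log(freqs.pi[:3] / freqs.pi[3])
    for k in range(3):
        fp, fm = f0.copy(), f0.copy()
        fp[k] += h; fm[k] -= h
        ep = np.exp(np.append(fp, 0.0)); em = np.exp(np.append(fm, 0.0))
        Qp = normalized_q(gtr, BaseFrequencies(ep / ep.sum()))
        Qm = normalized_q(gtr, BaseFrequencies(em / em.sum()))
        out.append((Qp - Qm) / (2 * h))
    return out


def _dpi_dtheta(pi: np.ndarray) -> np.ndarray:
    """d pi_i / d theta_k for the frequency log-ratio transform (3 x 4)."""
    out = np.zeros((3, 4))
    for k in range(3):
        out[k] = -pi[k] * pi
        out[k, k] += pi[k]
    return out


def _dr_dalpha(rhas: GammaRHAS, h: float = 1e-5) -> np.ndarray:
    """d category_rates / d log(alpha), central difference."""
    from .models import discretize_gamma
    if rhas.ncat == 1:
        return np.zeros(1)
    a = rhas.alpha
    rp = discretize_gamma(a * np.exp(h), rhas.ncat).category_rates
    rm = discretize_gamma(a * np.exp(-h), rhas.ncat).category_rates
    return (rp - rm) / (2 * h)


class GradientWorkspace:
    """Staged per-class computation: the inside pass (and the pattern
    log-likelihood column it yields) is done at construction; gradients —
    which need externally supplied site weights, e.g. posterior-weighted
    pattern counts — are computed on demand, reusing the cached partials.

    Everything flows through two tree passes: inside partials, outside
    partials, then per-edge 4x4 moment matrices ``M_ec`` that contract the
    flux across each edge.  Branch gradients are ``sum_c r_c <M_ec, Q
    P_ec>``; rate-matrix parameters reduce to a single 4x4 kernel ``K``
    through the spectral derivative of the matrix exponential, plus the
    explicit stationary-frequency term at the root.  Transformed
    coordinates are log exchangeabilities, frequency log-ratios and log
    alpha.
    """

    def __init__(self, paln: PatternAlignment, cm: ClassModel):
        self.cm = cm
        self.eng = _Engine(paln, cm)
        self.partials, self.logscale = self.eng.upward_full()
        root = self.eng.tree.root
        site_l = self.partials[root] @ self.eng.pi  # (ncat, P)
        with np.errstate(divide="ignore"):
            logl_cp = np.log(site_l) + self.logscale[root]
        self.log_L = logsumexp(logl_cp, axis=0, b=1.0 / self.eng.ncat)

    def value(self, site_weights: np.ndarray) -> float:
        return float(np.dot(site_weights, self.log_L))

    def gradients(self, site_weights: np.ndarray, want_gtr: bool = True,
                  want_freqs: bool = True, want_alpha: bool = True):
        eng, cm = self.eng, self.cm
        tree = eng.tree
        root = tree.root
        partials, logscale = self.partials, self.logscale
        logL = self.log_L
        F, Fscale = eng.downward(partials, logscale)
        edge_nodes = [v for v in range(tree.n_nodes) if v != root]
        ncat, rates, Q = eng.ncat, eng.rates, eng.Qm.Q

        grads: dict[str, np.ndarray | float] = {}
        gb = np.zeros(len(edge_nodes))
        K = np.zeros((4, 4))
        A = np.zeros((len(edge_nodes), ncat))  # <M_ec, Q P_ec> per edge/cat
        R_, L_ = eng.Qm.right, eng.Qm.left
        want_K = want_gtr or want_freqs
        log_ncat = np.log(ncat)
        for k, v in enumerate(edge_nodes):
            sc = Fscale[v] + logscale[v]
            f = np.exp(sc - logL[None, :] - log_ncat) * site_weights[None, :]
            Fw = F[v] * f[..., None]
            # moment matrix over the edge above v, per category
            M = np.matmul(np.swapaxes(Fw, 1, 2), partials[v])
            QP = np.matmul(Q, eng.P[:, v])
            A[k] = np.einsum("cst,cst->c", M, QP)
            gb[k] = float(np.dot(rates, A[k]))
            if want_K:
                b = float(tree.lengths[v])
                Mt = np.matmul(np.matmul(R_.T, M), L_.T)
                K += (Mt * _phi_matrix(eng.Qm.eigvals, b * rates)).sum(axis=0)
        grads["branch"] = gb

        if want_K:
            dQs = _dQ_matrices(cm.gtr, cm.freqs)
            vals = np.array([float(np.sum(K * (L_ @ dq @ R_))) for dq in dQs])
            if want_gtr:
                grads["gtr"] = vals[:5]
            if want_freqs:
                # explicit root-prior term: d/dpi of sum_s pi_s part_root[s]
                sc = logscale[root]
                f = np.exp(sc - logL[None, :] - log_ncat) * site_weights[None, :]
                droot = np.einsum("cp,cps->s", f, partials[root])
                grads["freqs"] = vals[5:] + _dpi_dtheta(cm.freqs.pi) @ droot
        if want_alpha:
            dr = _dr_dalpha(cm.rhas)
            b_e = tree.lengths[edge_nodes]
            grads["alpha"] = float(np.einsum("e,c,ec->", b_e, dr, A))
        return grads


def class_loglik_and_gradients(paln: PatternAlignment, cm: ClassModel,
                               site_weights: np.ndarray,
                               want_gtr: bool = True, want_freqs: bool = True,
                               want_alpha: bool = True):
    """Weighted class log-likelihood and its exact gradient with respect to
    all branch lengths and (optionally) the substitution parameters; see
    :class:`GradientWorkspace` for the mechanics.  Returns ``(value,
    grads)`` with keys ``branch`` (over ``tree.edge_nodes()``), ``gtr``
    (5), ``freqs`` (3) and ``alpha`` (scalar)."""
    ws = GradientWorkspace(paln, cm)
    return ws.value(site_weights), ws.gradients(site_weights, want_gtr,
                                                want_freqs, want_alpha)


def weighted_loglik_and_branch_grad(paln: PatternAlignment, cm: ClassModel,
                                    site_weights: np.ndarray):
    """Objective ``sum_p v_p log L_p`` and its exact gradient with respect to
    every branch length, computed from inside and outside partials.

    Returns ``(value, grad, edge_nodes)`` where ``grad[k]`` is the derivative
    for the edge above ``edge_nodes[k]``.
    """
    eng = _Engine(paln, cm)
    tree = eng.tree
    partials, logscale = eng.upward_full()
    root = tree.root
    site_l = partials[root] @ eng.pi  # (ncat, P)
    with np.errstate(divide="ignore"):
        logl_cp = np.log(site_l) + logscale[root]
    logL = logsumexp(logl_cp, axis=0, b=1.0 / eng.ncat)  # (P,)
    value = float(np.dot(site_weights, logL))

    F, Fscale = eng.downward(partials, logscale)
    Q = eng.Qm.Q
    edge_nodes = [v for v in range(tree.n_nodes) if v != root]
    grad = np.zeros(len(edge_nodes))
    rates = eng.rates
    for k, v in enumerate(edge_nodes):
        # dP/db = r_c * Q @ P  on the edge above v
        QP = np.einsum("st,ctu->csu", Q, eng.P[:, v]) * rates[:, None, None]
        dL = np.einsum("cps,csu,cpu->cp", F[v], QP, partials[v])
        # convert to d logL / db with the per-(cat,pattern) scale factors
        sc = Fscale[v] + logscale[v]
        f = np.exp(sc - logL[None, :] - np.log(eng.ncat))
        grad[k] = float(np.dot(site_weights, (f * dL).sum(axis=0)))
    return value, grad, np.array(edge_nodes)
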