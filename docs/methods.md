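# Methods

## The model

`mastmix` fits a *multitree mixture* to a DNA alignment: every site is
assumed to have evolved under one of `m` fixed bifurcating topologies, and
the likelihood of site `i` is the weighted sum

    L_i = Σ_j  w_j · L_ij(T_j, λ_j, R_j, H_j, F_j),      w_j > 0, Σ_j w_j = 1,

where `L_ij` is the standard pruning likelihood of site `i` on topology
`T_j` with branch lengths `λ_j`, GTR exchangeabilities `R_j`, stationary
frequencies `F_j`, and discrete-gamma rate heterogeneity `H_j`.  The full
log-likelihood is `l = Σ_i log L_i` over all `N` sites, treated as
independent and identically distributed; identical columns are collapsed
into weighted site patterns, which leaves every likelihood unchanged.

Tree weights estimate the fraction of sites associated with each
topology.  They are related to, but not identical to, gene-tree
frequencies: weights are driven by the phylogenetically informative sites
supporting each topology rather than by locus counts, and they require no
locus boundaries at all, which is what makes the model robust to
recombination within loci.

Six submodels control which parameter blocks are shared ("linked") across
classes.  Branch lengths and topologies are always per-class:

| submodel | substitution rates | base frequencies | rate heterogeneity |
|---------:|--------------------|------------------|--------------------|
| 1 | unlinked | unlinked | unlinked |
| 2 | unlinked | unlinked | linked |
| 3 | unlinked | linked   | unlinked |
| 4 | unlinked | linked   | linked |
| 5 | linked   | linked   | unlinked |
| 6 | linked   | linked   | linked |

The two remaining combinations (linked rates with unlinked frequencies)
are not expressible: a shared rate matrix is built from shared
frequencies, so the constructor simply has no way to state them.

Free parameters for BIC (`k·ln N − 2l`): `(m−1)` weights, `m(2t−3)`
branch lengths for `t` taxa, plus 5 exchangeabilities, 3 frequencies and
1 gamma shape per unlinked block (each counted once when linked).  The
BIC sample size is the alignment length `N`, consistent with the
per-site likelihood definition.

## Parameter estimation

All topologies are supplied by the user (topology search is out of
scope).  Optimization starts from a deliberately cheap, deterministic
initialization:

* substitution model: Jukes–Cantor (all exchangeabilities 1, uniform
  frequencies), gamma shape 1;
* branch lengths: Fitch parsimony changes attributed to each branch by a
  minimal reconstruction, divided by the number of sites, floored at
  10⁻⁶ substitutions/site;
* weights: the proportions of parsimony-discriminating sites assigned to
  each minimum-score topology (ties split fractionally; equal weights if
  no site discriminates);
* one extra "hard-assignment" pass: each class's parameters are first
  optimized against the parsimony site assignment, so classes start in
  distinct basins instead of all sitting on the same blended optimum.

The main loop then alternates, until the total log-likelihood improves by
less than `ε = 10⁻⁴`:

1. **weights** — the EM update `w_j ← (1/N) Σ_i p_ij` (mean posterior
   membership), iterated to its fixed point while the per-class site
   likelihoods are held fixed, which makes it the exact conditional
   maximum over the weight simplex.  Weights are floored at 10⁻⁶ and
   renormalized; a class whose weight collapses to the floor is frozen
   and flagged rather than deleted.
2. **inner stage** — for each class, branch lengths plus any unlinked
   exchangeabilities and frequencies are optimized against the expected
   class log-likelihood `E[l_j] = Σ_i p_ij log L_ij` (the EM surrogate)
   by bounded L-BFGS-B with exact analytic gradients.
3. **middle stage** — the per-class (or shared) gamma shape, likewise.
4. **linked blocks** — parameter blocks shared across classes do not
   admit the EM surrogate, so they are optimized by quasi-Newton search
   directly on the mixture log-likelihood, with gradients assembled from
   the posterior-weighted per-class gradients.
5. **joint refinement** — a quasi-Newton pass over *every* free
   parameter at once (log weights, log branch lengths, transformed
   substitution parameters).  This step exists because the mixture
   surface is extremely flat along directions that trade weights against
   branch lengths; block-coordinate EM alone creeps along that ridge and
   can need thousands of iterations to move the weights the last few
   hundredths.  A stalled quasi-Newton run frequently improves again
   when restarted, so the refinement is retried while restarts keep
   paying more than `ε`.

Every accepted step is guarded: a block update or refinement that fails
to improve its objective is rolled back, so the iteration trace is
non-decreasing by construction, and convergence is declared only when a
full iteration (blocks plus refinement) gains less than `ε`.

### Gradients

Branch-length gradients come from inside ("upward") and outside
("downward") conditional likelihoods.  For the substitution parameters,
the directional derivative of each edge's transition matrix
`P = exp(Q·b·r_c)` is taken through the spectral decomposition of the
reversible `Q` (the divided-difference kernel of the matrix exponential).
Because the derivative with respect to any rate-matrix entry factors
through the same per-edge moment matrices, all GTR and frequency
gradients collapse to a single 4×4 kernel per class; the stationary
frequencies contribute one extra explicit term from the root prior, and
the gamma shape enters through the derivative of the category rates.
Only the 4×4 construction `dQ/dθ` and `dr_c/dα` use central differences;
everything through the tree is exact.  The test suite checks the full
gradient against central differences of the likelihood itself.

### Numerical choices

* Likelihood underflow is handled by per-node scaling vectors accumulated
  in log space; rescaling every fourth internal node keeps double
  precision comfortably away from underflow for trees of the sizes
  handled here (≤ a few dozen taxa).
* Discrete gamma uses mean-of-interval category rates on
  equal-probability categories, renormalized so the weighted mean rate is
  exactly 1 (`ncat = 4` by default).  At fixed parameters the engine
  agrees with phangorn's `pml` to ~10⁻⁶ log units, which pins down this
  convention against an independent implementation.
* Branch lengths are bounded to `[10⁻⁶, 10]` substitutions/site,
  exchangeabilities to `[10⁻⁴, 10⁴]` relative to GT ≡ 1, the gamma shape
  to `[0.02, 100]`; all are optimized in log space, frequencies as
  log-ratios against T.
* Duplicate input topologies are rejected by default (identical
  topologies make the weights non-identifiable); a flag permits them for
  deliberately degenerate setups.
* Columns that are gaps/fully ambiguous in every taxon carry no
  likelihood information and are excluded at read time with a log
  message; partial ambiguity codes become partial-uncertainty tip
  vectors (1 on every compatible state).

## Simulators

`simulate_alignment` draws root states from the stationary frequencies,
assigns each site one gamma category (uniformly over categories, constant
across the tree — the discrete +G assumption), and evolves states down
each branch through the exact transition matrices.  Mixture alignments
assign sites to classes either iid from the weight vector or in
contiguous blocks; both return the true per-site labels.  Because the
likelihood treats sites as exchangeable, block and iid layouts with the
same marginal proportions are statistically equivalent to the model — a
property the tests exercise.

Misspecified topology sets are produced by sequential random
subtree-prune-regraft (SPR) moves, each move constrained to change the
unrooted topology (verified on the canonical split-set identity), with
outputs distinct from the source tree and from each other.

The introgression simulator is a purpose-built 4-population structured
coalescent, not a general coalescent engine: one lineage per species,
species tree (((1,2),3),4) with divergence times `t12 < t123 < t1234` in
coalescent units, and a single pulse at `t_m < t12` in which the lineage
sampled from species 4 migrates into population 2 with probability `r`
(backward in time).  Defaults (`t_m, t12, t123, t1234 = 0.5, 1.0, 1.5,
2.0`) put both internal branches at 0.5 coalescent units, giving
substantial incomplete lineage sorting: at `r = 0` each minor topology
appears with probability close to `(1/3)·e^{−0.5} ≈ 0.20`, and the test
suite checks the sampler against that closed form with a distant
outgroup.  Gene trees are rescaled from coalescent units to
substitutions/site by a configurable factor (default 0.002) and short
per-gene alignments are simulated under one shared GTR+G model and
concatenated, so the fitted mixture sees realistic low-divergence data
with no locus boundaries.

### Generating distributions (harness defaults)

The experiment harness draws, per replicate: exchangeabilities
log-uniform on [0.5, 5] (GT ≡ 1), frequencies Dirichlet(15·1) around
uniform, gamma shape uniform on [0.5, 2], branch lengths exponential with
mean 0.1 clipped to [0.02, 0.8] substitutions/site, and mixture weights
Dirichlet(5·1).  The first topology is uniform at random; additional
mixture topologies are 1–3 random SPR moves away.  These are fixed,
documented choices of plausible values — chosen once, not tuned — and
they define what the recovery numbers mean: weight errors quoted below
are conditional on this level of sequence divergence and topology
similarity.

### What the simulations do not capture

Real alignments have autocorrelated class membership (recombination
blocks), alignment error, indels, base-composition heterogeneity across
lineages, and selection; none of these are simulated.  Passing recovery
tests therefore demonstrates the correctness and statistical efficiency
of the estimator under the model's own assumptions, not robustness to
model violation beyond the specific misspecifications studied (decoy
topologies, single-tree data fitted with mixtures).

## Experiment scales

The experiment harness and acceptance script run the same study designs
as the full simulation studies but at reduced scale, chosen as fixed
defaults: the 5 kb unlinked-recovery grid uses one replicate per
(trees × taxa) cell under a capped optimizer budget (one outer iteration
with a bounded joint refinement — truncated optimization can only
inflate the recovery error, so the grid average remains an upper-bound
check); the easiest-case recovery (2 trees × 20 taxa) uses two 30 kb
replicates per submodel instead of 100 kb; the hardest case (10 trees ×
6 taxa) uses two 5 kb unlinked replicates and one 30 kb linked
replicate, fully converged; the all-topologies selection study uses five
20 kb replicates with 2 sequentially added decoy trees (additions only
ever worsen BIC once the true pair is present) and a budget-capped
15-topology fit whose sole role is ordering the decoys; and the
misspecification study uses 3 replicates × 3 mixture sizes at 8 kb.
Weight RMSE scales roughly as the inverse square root of the alignment
length, so the shortened alignments bound the full-length errors from
above.

## Known limitations

* No topology search and no estimate of the number of classes: the
  topology set is an input, as in the fixed-topology workflow this
  package implements.
* Nucleotide data only (no amino-acid or codon models), +G only (no +I
  or free-rate heterogeneity), time-reversible models only.
* Weight identifiability degrades as topologies become similar — with
  decoys one SPR move from the truth, the true tree's weight advantage
  can vanish on short alignments; BIC comparisons remain reliable in the
  regimes tested.
* The structured coalescent is hard-wired to the 4-taxon single-pulse
  design; it is a study-specific simulator, not a general tool.
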