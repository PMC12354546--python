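# Methods

`cladevol` implements a family of clade-comparative molecular-evolution
analyses of the kind used to ask how a life-history transition (here, the
loss or reduction of tooth replacement in acrodont lizards and mammals)
reshapes the evolution of a protein family: branch-specific dN/dS, Gu-style
functional divergence between clades, its decomposition into per-clade
functional branch lengths, detection of convergent amino-acid profile
shifts, and local molecular-clock rates. Every stage has a forward
simulator, so all estimators are validated on data whose truth is known.

## Codon branch models (dN/dS)

The substitution process over the 61 sense codons of the standard code is
the Goldman–Yang model: for codons differing at exactly one position the
rate is π_j (synonymous transversion), κπ_j (synonymous transition), ωπ_j
(nonsynonymous transversion) or κωπ_j (nonsynonymous transition); zero
otherwise. Each generator is scaled to one expected substitution per codon
per unit branch length. Branch models assign each labeled branch class its
own ω while sharing κ and the codon frequencies (F3x4 from positional
nucleotide counts by default, F61 optional; a 10⁻⁶ floor avoids zeroed
codons).

Likelihoods use Felsenstein pruning with per-node rescaling; gap and
ambiguous codons are missing data (all-ones partials); the root uses the
stationary frequencies. Transition matrices come from the symmetric
eigendecomposition available for reversible generators. The exhaustive sum
over interior-node states is kept as a test oracle on small trees.

Optimization is joint over log κ, log ω per class, and log branch lengths
with L-BFGS-B in box bounds (κ ∈ [10⁻³,10³], ω ∈ [10⁻⁴,10³], t ∈
[10⁻⁸,50]). Branch-length gradients are analytic — one postorder and one
preorder sweep give ∂lnL/∂t for every edge at about twice the cost of a
likelihood evaluation, with rescaling factors cancelling in the per-edge
ratios — while κ/ω components use forward differences. Convergence
tolerance is ~10⁻⁶ lnL units. Multi-start (warm start, a κ=2/ω=0.5
default, seeded random) is available; ladder fits warm-start from the
previous model so nested lnL is monotone by construction.

Convention: the one-ratio model is fitted on the unrooted (basal
trifurcation) tree, multi-ratio models on the rooted tree. Under
reversible models only the sum of the two root-adjacent branch lengths is
identifiable, so fitted branch lengths are keyed by each edge's child leaf
set and transfer between the two forms; the free-parameter count uses the
unrooted edge count, making LRT df equal the difference in ω-class counts.
Negative LRT statistics (optimizer noise) are clamped to zero with a
warning. A ½χ²₀+½χ²₁ boundary-mixture p-value is available but off by
default. The free-ratio model (one ω per branch) is implemented but not
part of the reporting ladder.

Nesting across the ladder requires that each finer labeling partition the
coarser one. Named-clade labelings where stems and connective branches
revert to the background break this, so the bundled fixtures label the
broader clade first and overwrite its subclades; the connective stem
branches thereby stay with the first subclade's class. This is a
convention, not an inference claim about stem lineages.

## Local molecular clocks

On a time-calibrated tree the expected substitutions on a branch are
rate × time span, with rates shared within labeled branch classes: one
class is a strict clock, k classes a local clock. The nucleotide process
is GTR (six exchangeabilities, the G–T one fixed at 1, generator scaled to
unit rate). Base frequencies are estimated by default (softmax
parameterization; option to fix at empirical counts). Rate gradients are
analytic via the branch-length gradients (∂lnL/∂r_c = Σ τ_e ∂lnL/∂t_e);
GTR parameters use forward differences. Node ages are inputs; rates and
ages are confounded up to a global factor, which a rescaling-invariance
test asserts. Rate SEs come from the curvature of lnL in log-rate space
with other parameters fixed (delta method), so they are conditional SEs.
LRT df between clock models equals the difference in rate-class counts.
Among-site rate variation is not modelled.

## Type-I functional divergence

Type-I divergence between two monophyletic clusters is a site-specific
decoupling of evolutionary rates after the split. Per-site substitution
counts on each cluster's subtree are minimum parsimony changes (unit-cost
Sankoff DP, exact for multifurcations; only columns gap-free across both
clusters are counted). The model: each site draws a rate λ ~ Gamma(α, α)
(mean 1); with probability θ the two clusters' rates are independent draws
(state F), otherwise shared (state S); counts are Poisson(D_k λ) with D_k
the cluster's expected changes at unit rate. Marginals are negative
binomial; the shared-rate joint has the closed bivariate form used both in
the likelihood and as a θ=0 consistency oracle. (θ, α, D₁, D₂) are
maximized by bounded L-BFGS-B with a Nelder-Mead null fit and multiple
starts; the θ=0 LRT is referred to χ²₁ (boundary-mixture option off by
default); SE(θ) comes from the observed-information matrix; per-site
posteriors of state F rank candidate sites.

The empirical posterior cutoff removes the top-posterior site, refits, and
repeats until the LRT p-value exceeds α (default 0.05); removed sites are
the predicted divergence-related residues and the last removed site's
posterior is the reported cutoff. Refits on fewer than 30 sites stop the
procedure.

## Type-II functional divergence

Type-II divergence is "conserved but different": sites fixed within each
cluster for residues with radically different physicochemical properties.
The estimator here is an explicit stand-in with the conventional interface
(θ_II, SE, Z, p), not a reimplementation of the full ancestral-sequence
model. Gap-free sites are classified as fixed-same (C0), fixed-different
within one property group (CC), fixed-different across groups (CR,
radical), or variable (V); within-cluster-monomorphic columns determine
the cluster residue (equal to the unique parsimony root state). A
point-mass-on-CR component with weight θ_II sits over a background
multinomial. A fully free background makes θ_II non-identifiable, so the
background's CC:CR split is pinned to the null radical fraction — the
probability that two distinct residues drawn from the observed frequencies
fall in different property groups. θ_II is fitted by EM; SE from the
profile-likelihood curvature; significance by a two-sided Z-test. The
default partition is nonpolar AVLIMFWP / polar GSTCYNQ / positive KRH /
negative DE, configurable.

## Functional distance and branch lengths

A pairwise coefficient θ maps to a functional distance d_F = −ln(1−θ)
(implemented via log1p so d_F is strictly increasing down to tiny θ),
which is additive over clusters: d_F(A,B) = b_F(A) + b_F(B). For three
clusters the decomposition is the closed form
b_F(A) = (d_F(A,B)+d_F(A,C)−d_F(B,C))/2 and cyclic permutations; for n ≥ 3
a least-squares fit minimizes Σ(d_ij − b_i − b_j)², coinciding with the
closed form (zero residual) at n = 3. Negative b_F, possible when the
distances violate star additivity, is reported as computed with a warning,
never truncated. θ ≥ 1 is an error (infinite distance); small negative θ
estimates can be clamped to 0 on request. No SEs are propagated to b_F.

## Convergent profile shifts

Sites evolve under amino-acid frequency profiles via an F81-type process
(rate into j proportional to π_j, unit-scaled). A convergence scenario
names ≥ 2 disjoint monophyletic foreground clades; each clade's stem is a
transition branch. Four disjoint path classes are scored per column: no
shift with some eventless transition branch (null), shift with some
eventless transition branch (PC), no shift with every transition branch
substituted (OC), and shift with every transition branch substituted
(PCOC). "Every transition branch substituted" replaces the diagonal of
the transition matrix with P_ii(t) − e^{−q_i t}; the complements subtract
that likelihood from the unconstrained one. Likelihoods average uniformly
over profile assignments (K single profiles; K(K−1) ordered pairs c ≠ a
with the background profile at the root). A per-site rate multiplier over
a log-spaced 7-point grid (0.25–8) is marginalized with a uniform prior.

Two posterior views are reported: the joint posterior over the four
disjoint classes (equal priors, sums to 1), and — as the headline scores
used for thresholds — each alternative's posterior against the
unconstrained single-profile null in a two-model comparison. The pairwise
convention is what makes a threshold like pp ≥ 0.8 meaningful: in the
joint view the PC class, which differs from PCOC only in the unobservable
timing of the shift, necessarily siphons posterior mass from true
convergent sites.

The default profile set is one peaked profile per physicochemical
subgroup (aliphatic AVLIM, aromatic FWY, PG, ST, C, NQ, KR, H, DE) plus a
uniform catch-all, Dirichlet-smoothed with pseudo-count 0.01. Peaked
profiles matter: broad two-group profiles allow the null to explain
genuinely convergent columns with one profile and no shift. Columns
entirely gap/ambiguous in a foreground clade are flagged (no
one-change evidence from that clade). Branch lengths are taken from the
input tree.

## Synthetic data

All simulators draw exact continuous-time Markov chain paths per branch
(Gillespie sampling; conditioning on ≥1 event on a branch uses a
truncated-exponential first waiting time, which is the exact conditional
law), so event-level truth is available, and all are deterministic given a
seed.

The study-shaped fixture is a rooted ultrametric tree with a mammal-like
clade and an iguanian clade split into pleurodont-like and acrodont-like
groups, the acrodonts into chameleon-like and agamid-like subclades.
Defaults are scaled down to 3/3/6/6 taxa (the full study had 24 acrodonts,
17 pleurodonts, 12 mammals) with root-to-tip depth 1.0 expected
substitutions at the neutral rate; the matching chronogram uses ages of
312 (amniote root), 160 (iguanian split), 100 (acrodont split) and 60
(crown clades) million years. Generator presets carry the study-scale
effect sizes: three-class ω (0.33, 0.46, 0.40), four-class ω (0.26, 0.42,
0.60, 0.29), θ presets 0.74 and 0.80.

Simulators cover: codon alignments under branch-class ω; per-site
count tables from the Type-I model (with an optional planted set of
fast/slow-contrast sites for localization tests); protein alignments with
a Type-I rate decoupling on one clade; protein alignments planting
conserved-but-different radical sites; protein alignments with convergent
profile shifts (forced stem changes on truth sites); and nucleotide
alignments on a chronogram with clade-specific clock rates.

What a green simulation test does and does not establish: the simulators
generate data exactly under the fitted models (no indels, no alignment
error, no selection heterogeneity within classes, uniform codon
frequencies unless configured), so recovery tests validate estimator
correctness and calibration, not robustness to the model violations real
alignments carry.

## Statistical power at the default scales

At 12 taxa × 500 codons the three-class ω estimates are unbiased with SDs
of 0.025–0.04 — at the information bound for the design. With presets
separated by only 0.06–0.07, the probability of recovering the full class
ordering in one replicate is ≈ 0.77, so a "≥ 8 of 10 seeds" check is
intrinsically marginal at this scale; larger alignments or deeper trees,
not a different estimator, would be needed to make it reliable. The
two-vs-one-ratio LRT holds its nominal size (5/50 rejections at α = 0.05
under the null).

## Numerical choices

Pattern compression collapses identical columns; per-node rescaling
prevents underflow; all gradients used by optimizers are scale-free
ratios. Optimizer tolerances: ftol 10⁻¹¹ (relative), gtol 10⁻⁷.
Hessian-based SEs use central differences (step 10⁻⁴) and return NaN when
the information matrix is not positive definite (e.g. θ̂ at a boundary).
Every pipeline table embeds a configuration hash and the master seed; all
randomness flows from that single seed through a SeedSequence, so reruns
are byte-identical.

## Known limitations

- Site and branch-site dN/dS models are out of scope (branch models only).
- The Type-II estimator is a stand-in (see above), prominently so.
- PCOC-style detection uses the bundled 10-profile set, not an empirical
  C10/C60 library; scenarios are user-specified, not enumerated.
- Clock SEs are conditional (curvature in rates only).
- No multiple-testing correction is applied across genes (a Bonferroni
  column is emitted for transparency but does not drive any flags).
- The percent-identity convention is pairwise deletion with 'X' counted as
  comparable-but-never-matching; other tools' conventions differ.
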