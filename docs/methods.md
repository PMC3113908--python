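# Methods

## Model

A discrete character with k states evolves along a rooted phylogeny as a
continuous-time Markov chain. Off-diagonal rates `q_ij >= 0` are free
parameters except where a transition-constraint mask imposes a structural
zero; diagonals are minus the row sums, so `P(t) = exp(Qt)` is stochastic for
every branch length `t >= 0`. A forbidden single step does not force
`P_ij(t) = 0` — multi-step paths through intermediate states remain possible —
except out of an absorbing state (a state whose entire row is masked), whose
row of `P(t)` stays an indicator forever.

Two built-in behavioral characters share one pair of constraint rules: no
direct move from the solitary or parasitic state to advanced eusociality, and
no move out of advanced eusociality. On the four-state ("traditional")
character this forbids 5 of 12 off-diagonal cells; adding the intermediate
"social" state (the five-state "complex" character) forbids 6 of 20. Only the
quoted rules are hard-coded; every cell is configurable, so the relaxed model
(solitary -> advanced allowed again) is a one-line config change. Five binary
life-history traits (two-generation colonies, division of labor, mass
provisioning, undifferentiated castes, solitary founding) use k = 2, a full
mask, and reversible-jump rate classes.

Tip codings map each taxon to a nonempty state subset. A subset of size > 1
is an *ambiguity* (uncertainty about the clade's state), not a frequency
mixture: the tip partial is an indicator vector with 1 at each allowed state,
the BayesTraits multistate convention. Enlarging a tip's state set therefore
can only increase the likelihood (tested as an invariant).

The likelihood is computed by post-order pruning with per-node rescaling
(accumulated log factors prevent underflow on large trees). *Fossilizing* a
node — required both for marginal ancestral probabilities and for the Bayes
Factor protocol — multiplies the node's partial by the indicator of its
allowed states after its children are combined. Marginal node probabilities
are defined as the renormalized per-state fossilized likelihoods; the sampler
computes them for all nodes at once with a single down-pass, which is tested
node-by-node against the fossilization definition and against exhaustive
enumeration.

**Root prior.** The constrained model is non-reversible (the absorbing state
makes the stationary distribution degenerate), so the conventional
stationary-frequencies root treatment is unusable. The default is uniform
(1/k), exposed in configuration; indicator priors implement fixed-root
analyses.

## Priors and proposal kernels

* `uniform_fixed` — iid uniform(lo, hi) on every free rate, default (0, 100).
  The rate move proposes all rates jointly with a sliding window reflected at
  the bounds (symmetric; one likelihood evaluation per move), and every
  second rate move additionally applies a single-rate multiplier refinement
  (Hastings ratio r'/r). The refinement matters because rates under a wide
  uniform prior span orders of magnitude: an additive window tuned to the
  prior scale cannot carry a rate from ~50 to ~0.3, and without the
  multiplier kernel chains can remain stuck on the saturated high-rate
  plateau, where `P(t)` rows approach a common distribution and the
  likelihood becomes insensitive to ancestral states.
* `exp_hyper` — rates iid exponential with mean m, and m ~ uniform(0, 10).
  Rates move by per-rate multiplier sweeps. Because m does not enter the
  likelihood, it is refreshed every iteration with an exact Gibbs draw from
  its full conditional, a truncated inverse-gamma(n-1, sum of rates)
  (inverse-CDF via regularized incomplete gamma functions; the n <= 1 corner
  is sampled on a grid). The "sampled hyperparameter" reading is used: m is
  part of the chain state, so the rate prior is an exponential *mixture* —
  both the uniform(0,10) hypermean marginal and the mixture CDF of the rates
  are verified by prior-only sampling tests.

Tree uncertainty is integrated by proposing a tree uniformly from the input
posterior tree sample and accepting by likelihood ratio (weights honored if
provided). Move weights tree : rate : structure default to 1 : 2 : 1. The
window width is tuned toward 20-40% acceptance during the first 10% of the
run only, and frozen afterwards so detailed balance holds for every recorded
sample. Chains are reproducible bit-for-bit from (seed, settings); replicate
and fossilization-arm seeds derive from a master seed by a counter scheme,
and replicate i shares its seed across arms so Bayes Factor comparisons are
paired.

**Reversible jump.** A structure is a zero-set plus a partition of the
remaining allowed cells into rate classes (cells in the zero class have rate
exactly 0). The prior over structures is uniform; class rates are iid under
the active rate prior. Moves: split a class (uniform nonempty bipartition),
merge two classes, move a cell to/from the zero class, and redraw a class
rate — new class rates are proposed from the prior, so prior densities cancel
and acceptance reduces to the likelihood ratio times a counting factor. On
two cells the five reachable structures are enumerable, and a prior-only
chain reproduces the uniform 20% occupancy of each (tested).

**Burn-in.** Default: discard the first 25% of samples. A Geweke alternative
compares the first 10% with the last 50% of the log-likelihood trace
(autocorrelation-adjusted z), returning the first start index with |z| < 2
and advising a longer run if none exists.

**Marginal likelihood.** The harmonic mean of the post-burn-in likelihoods,
computed in log space (`log n - logsumexp(-logL)`). This matches the protocol
of the Bayes Factor tests; no other estimator is provided. Bayes Factors are
reported as `2 * (difference of log harmonic means)` (the raw difference is
available behind a flag), with support categories: <= 0 against, 0-2 weak,
2-5 positive, > 5 strong; the > 5 "strong" threshold anchors the published
convention, the cut at 2 is this package's documented choice. A state whose
fossilization makes the data impossible in every replicate is reported as
"state impossible" with an infinite BF against it rather than raising.

## Trees, ages and intervals

Trees are array-backed (postorder index arrays) for the likelihood inner
loops, with parsing/serialisation delegated to dendropy (Newick and NEXUS
with translate tables; underscores kept literal by default, matching
BayesTraits-style inputs; branch lengths round-trip at 10 significant
digits). Zero-length branches are legal and use `P(0) = I` exactly; negative
lengths are rejected.

Node ages require ultrametricity within a relative tolerance of 1e-6 of tree
depth (chronogram files carry rounded lengths); violations name the worst tip
pair. The HPD interval of a sample is the shortest contiguous window of the
sorted values containing `ceil(mass * n)` points, left-most on ties; clade
age reports over a chronogram sample use the per-tree MRCA age sample (mean
and 95% HPD), degenerating to (min, max) for samples of fewer than 20 trees.

## Numerical choices

* Transition probabilities: the robust path is scipy's Pade
  scaling-and-squaring `expm`, used by the public `transition_matrix` and as
  a fallback. The MCMC hot path computes one eigendecomposition of Q per
  likelihood evaluation and reconstitutes `P(t)` for all branches at once
  (numba kernel), falling back to `expm` whenever the eigenvector
  reconstruction error exceeds 1e-11 of the matrix scale or the eigenbasis
  1-norm condition estimate exceeds 1e8 — constrained Q can in principle be
  defective, but the continuous rate posterior makes exact defectiveness a
  measure-zero event, so the guard triggers rarely. The two paths agree to
  ~1e-12 on random constrained matrices (tested), and entries are clipped to
  [0, 1].
* The enumeration oracle (`enumeration_loglik`) sums over all joint internal
  state assignments with per-branch scipy `expm`; it shares no code with the
  pruning path and refuses more than 12 internal nodes.
* Likelihood exactly 0 (unreachable observed states, contradictory
  fossilizations) returns -inf rather than raising; reachability of observed
  tip states from the root-prior support is checked separately and reported
  as warnings.

## Synthetic data: what it emulates, and what it does not

The generator stands in for the study's undeposited inputs — a Bayesian
posterior tree sample and per-taxon codings. Trees are complete birth-death
simulations conditioned on the number of surviving tips (dendropy's forward
simulator; default birth 1.0, death 0.3 per unit time, rescaled to unit depth
for likelihood work or to millions of years for chronograms). A
pseudo-posterior sample multiplies each branch by an independent
log-normal(0, sigma) factor (default sigma 0.1), emulating posterior
branch-length spread while keeping the topology fixed so MRCA queries resolve
identically in every tree; topology rearrangement is deliberately off.
Character histories are simulated by Gillespie along each branch — forbidden
transitions have probability exactly 0 by construction, which the integrity
tests sweep. Polymorphic codings are created by adding one mask-adjacent
state with probability 0.1 per tip, keeping synthetic ambiguity coherent with
the transition graph. The deterministic 23-tip apid-like fixture reproduces
the study's clade structure (corbiculate topology
((bumble+stingless),(honey+orchid)), parasitic clades, carpenter-bee and
allodapine polymorphisms) with crown ages echoing the published dates
(corbiculates 87 Mya, allodapines 53, stingless bees 58, honey bees 22,
bumble bees 21, orchid bees 28).

What passing these tests does **not** show: the generator shares none of the
features that make real molecular posteriors hard (topological uncertainty,
correlated branch-length errors, model misspecification of the behavioral
character itself), and the fixture's 23 tips cannot reproduce the published
posterior probabilities or Bayes Factors, which depend on the full 190-taxon
tree sample.

## Design of the synthetic studies

* **Parameter recovery.** 20 datasets (100 tips, unit depth, true rates
  uniform in [0.5, 5] on the constrained 4-state mask, 10% polymorphism),
  each fitted with 2e5 iterations. Fitting uses the same uniform(0.5, 5)
  prior that generated the rates: frequentist coverage of Bayesian credible
  intervals is only guaranteed to be nominal when the truth is drawn from the
  fitting prior, and the study is designed as exactly that calibration
  experiment. (Under a mismatched wide U(0, 100) prior the weakly identified
  cells drift toward the saturated plateau and coverage drops to ~50% — a
  property of marginal posteriors, not a sampler defect.) Intervals are 90%
  HPDs of the thinned rate samples. Measured coverage is ~90%;
  ancestral-state calibration (modal state vs simulated truth among nodes
  with modal PP >= 0.9) is ~99%.
* **Bayes Factor study.** A slow character (all 12 rates 0.1 on the fully
  connected 4-state mask) simulated from a primitively eusocial root on
  100-tip trees, with draws *conditioned on the signal being present*
  (marginal root PP >= 0.99 at the generating parameters) — the amount of
  change a birth-death tree accumulates varies widely between draws, and a
  Bayes Factor test can only be expected to show strong support when the data
  actually carry it. Fitting uses a scale-matched uniform(0, 0.5) rate prior,
  which is essential for the quantity itself: with a very wide prior, the
  harmonic-mean marginal likelihood of *every* fossilized arm is dominated by
  the saturated high-rate region, where the likelihood is invariant to the
  root state, and the BF of any desk-scale dataset collapses toward 0. Under
  this design the test yields mean BF(Prim vs Adv) ~ 8-11 over paired
  replicates ("strong") across independent master seeds, and BF antisymmetry
  holds exactly per replicate.
* **Prior-only checks** run the full kernel set with the likelihood term
  disabled and verify the uniform(0,100) rate marginals, the uniform(0,10)
  hypermean marginal, and the reversible-jump structure prior by
  Kolmogorov-Smirnov and enumeration tests.
* **Exact-posterior toys.** A 2-tip tree with a one-way binary character has
  a single free rate, so its posterior and marginal likelihood are available
  by quadrature; the chain's binned marginal matches within total variation
  0.02, and the harmonic-mean estimate is within 0.1 nats on a uniform(0, 5)
  prior — chosen because the harmonic-mean estimator has finite variance
  there, which a much wider prior would destroy.

## Problem sizes

Test and acceptance runs use 1e5-2e5 iterations per chain, 20-50-tree
pseudo-posterior samples, 100-tip recovery trees, and 5-20 replicates —
chosen as the smallest sizes at which the statistical checks above have
comfortable margins. Production settings (the published protocol's 1e8
generations, 1e4-tree samples, 5 or 20 replicates) are ordinary configuration
values.

## Known limitations

* Marginal (per-node) reconstruction only; no joint max-posterior ancestral
  reconstruction and no stochastic character mapping along branches.
* The harmonic-mean marginal-likelihood estimator is used deliberately to
  match the published protocol; it is high-variance under diffuse priors, and
  no stepping-stone alternative is provided.
* Tree proposals resample a fixed list of trees; the sampler never perturbs
  topologies or branch lengths itself.
* The Geweke burn-in detector inspects only the log-likelihood trace.
* `record_all_nodes` (per-node marginals for whole-tree calibration) requires
  a single-topology tree sample, since node indices must be stable.
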