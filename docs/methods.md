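# Methods

`plumevo` implements a Bayesian comparative analysis of discrete plumage-pattern
evolution on a phylogeny. This note documents the model, the sampler, the
multimodel-inference calculus, the synthetic-data generator, and the numerical
and design choices, so that results can be interpreted and reproduced.

## The character and its coding

Each species is coded into one of four pattern states:

| state | meaning |
|---|---|
| `UNIFORM` | uniform coloration, no patterning |
| `IRREGULAR` | heterogeneous pigmentation without a repeated motif (e.g. mottling) |
| `REGULAR` | a regularly repeating motif (bars, scales, spots) |
| `BIMODAL` | both an irregular and a regular component, within one sex or across the sexes |

Coding is driven by per-sex motif sets (`NONE`, `MOTTLE`, `BAR`, `SCALE`,
`SPOT`, plus `OTHER_IRREGULAR` / `OTHER_REGULAR` escape codes for motifs
outside the canonical vocabulary). The species state is determined by the
union of the two sexes' pattern components: both components present gives
`BIMODAL`; a species patterned in only one sex counts as patterned. The
classification is symmetric in the sexes. Scoring conventions that reflect
manual data collection (breeding plumage, nominate subspecies) are carried as
record metadata, not enforced logic.

Clade-level frequency tables report, per clade at the order / subfamily /
tribe level, the percentage of species in each state; percentages are kept at
full precision internally and rendered to 0 decimals (zeros as a dash).
Bimodal species are further decomposed into three sex-phenotype categories:
(a) both sexes individually bimodal, (b) exactly one sex bimodal, (c) neither
sex bimodal but one regular and the other irregular.

## The evolutionary model

The character evolves along a rooted phylogeny with branch lengths under a
continuous-time Markov process with generator Q (4x4; off-diagonal q_ij >= 0,
rows sum to zero). A *rate configuration* assigns each of the K = 12 directed
transitions either to zero (the transition does not occur) or to a rate class
whose members share a single rate value. The structure — the zero set plus
the partition of the nonzero transitions into classes — is the object of
inference; rates are in transitions per unit branch length, so rate
magnitudes are only meaningful relative to the supplied tree's scale
(multiplying branch lengths by c and rates by 1/c leaves the likelihood
unchanged). Trees are used as supplied: no ultrametric enforcement and no
branch-length normalisation by default. Zero-length terminal branches are
replaced by 1e-6 x tree height (logged) to keep transition matrices
nondegenerate.

The likelihood is computed by Felsenstein's pruning algorithm with per-edge
rescaling (underflow-safe); per-edge transition matrices P(t) = exp(Qt) are
obtained from a batched eigendecomposition of Q, with a scipy `expm` fallback
when the eigenvector matrix is ill-conditioned, and exact identities on
zero-length edges. The public `transition_matrix` uses scipy's
scaling-and-squaring `expm` directly. The pruning pass is checked against an
exhaustive sum over internal-node state assignments on small trees.

The root is handled with a most-recent-common-ancestor style marginalisation:
the reported root-state vector is proportional to root_prior(s) x L_root(s).
The root prior defaults to uniform (0.25 per state), matching the convention
in which fully decayed root information reports 0.25 per state; the
stationary distribution of the current Q, or a user vector, can be chosen
instead.

## The reversible-jump sampler

The sampler explores structures and rate values jointly.

* **Structure prior.** Uniform over the Bell(K+1) = 27,644,437 distinct
  structures (the count decomposes as sum_z C(K, z) Bell(K-z): a binomial
  choice of the zero set times a Bell-number count of partitions of the
  rest). A per-dimension prior could be substituted, but the uniform
  per-signature prior is the convention this analysis follows.
* **Rate prior.** Each class value carries a gamma prior whose shape and
  scale are themselves sampled (a hyperprior): shape ~ U(1, 2), scale
  ~ U(eps, 2 x empirical scale), where the empirical scale is Fitch parsimony
  state changes divided by total tree length. The shape lower bound of 1
  keeps the gamma density finite at zero, so a near-zero "positive" rate
  cannot imitate a zero-rate model at no cost. Hyperparameters are updated by
  reflected Metropolis steps (every 10th iteration by default).
* **Moves.** 60% of iterations propose a rate-value update: one class value
  perturbed by a symmetric uniform kernel of scale `ratedev`, reflected at 0
  (Hastings ratio 1). 40% propose a structural move, chosen uniformly among
  the currently valid types: zero-out a transition, un-zero a transition into
  an existing or new class, merge two classes, split a class. New class
  values are drawn from the current gamma prior, which makes the
  reversible-jump Jacobian unity; acceptance then involves only likelihood,
  prior, and proposal-count terms. The move-type mixture is state-independent
  (a rate move drawn with no class present is a null iteration) — making it
  state-dependent would silently bias the structure posterior. With the
  likelihood switched off the chain samples the uniform structure prior
  exactly; this is verified by chi-square test, and the likelihood-on sampler
  is verified against exact quadrature posteriors on a 2-state problem.
* **Adaptation.** `ratedev` is adapted in blocks of 200 iterations during
  burn-in only, targeting a rate-move acceptance of 0.20–0.40, and is frozen
  afterwards so the retained sample obeys detailed balance.
* **Protocol.** Full-scale defaults: 4 chains x
  10,050,000 iterations, 50,000 burn-in, sampling every 1000th model, then
  every 20th retained model (2,000 models per analysis). A desk-scale
  profile (200,000 iterations, 5,000 burn-in, sample every 100th, thin by 2;
  ~1,000 retained models per chain) is the default for routine use and for
  the test suite; it converges on the problem sizes used here and keeps a
  full four-chain fit to a 170-tip tree within a few minutes.

Chains are seeded independently from one master seed and are exactly
reproducible. Every retained sample records the structure, class values,
log-likelihood, and root-state vector.

## Multimodel inference

Each retained model reduces to a canonical signature (zeros, plus classes
renumbered by first appearance). Posterior probability of a unique model =
its sample frequency / sample size; prior = 1/Bell(K+1); Bayes factor =
posterior/prior. Models with BF >= 2 form the top model set (the raw-odds
convention; a 2·lnBF convention is available as an option). Per-transition
marginal probabilities MP(zero) and MP(positive) are frequency-weighted
counts divided by the full retained-sample size; over the full sample they
sum to 1 per transition, over the top model set they need not. The averaged
ancestral vector is the arithmetic mean of per-sample root vectors. The
transition summary can be exported as a DOT digraph (black edges where
MP(positive) > MP(zero), width proportional to the mean positive rate, both
MPs annotated); every summary records which reference set produced it.

Note that in a 27.6-million-model space a diffuse posterior makes almost
every sampled signature unique, so each observed signature's BF is large and
the top model set can coincide with the full sample; with strongly
concentrated posteriors (as reported for real order-level data) the top
set is far smaller.

## Synthetic data

The generator stands in for the published order-level phylogenies and
field-guide scorings; nothing is downloaded.

* **Trees.** Pure-birth (Yule) trees (dendropy's birth–death simulator with
  death rate 0), 100–200 tips, unit birth rate, deterministic per seed.
  These reproduce the depth scaling (height ~ ln n) of real order-level
  trees but none of their rate variation or taxon sampling structure.
* **Characters.** Exact stochastic simulation (exponential waiting times)
  along each branch under a preset generator. Presets encode contrasting
  ground-truth structures: `fig2_hypothesis` (gains and losses along
  uniform–singular–bimodal paths, no uniform<->bimodal shortcut, no
  irregular<->regular interchange), `anseriformes_like` (regular and bimodal
  arise directly from uniform; regular never degrades to irregular),
  `galliformes_like` (irregular/regular arise from uniform, bimodal only via
  the singular types), `full_model` (all 12 transitions at one rate),
  `null_uniform` (no evolution), and `root_informative` (the galliformes
  structure at one third pace, for ancestral-state demonstrations). Rate
  magnitudes are set so a root-to-tip path expects roughly three state
  changes (~1 for `root_informative`) — informative but not saturated.
* **Sex decomposition.** Tip states are decomposed into per-sex motif codes
  consistent with the classification rules; bimodal tips draw their
  sex-phenotype category at a configurable 51:37:12 ratio, and singular
  -patterned species are patterned in one sex only with probability 0.3.

Because the generator matches the fitted model family exactly, passing
recovery tests demonstrates correctness of the machinery under the model's
own assumptions — not robustness to model violation (rate heterogeneity
across lineages, tree error, scoring error) that real data would add.

## What recovery can and cannot show at this scale

With ~3 expected changes per root-to-tip path on a 170-tip tree:

* Strongly exercised transitions are recovered cleanly (MP(positive) ~ 1).
* Transitions that the truth fixes to zero reach MP(zero) of only ~0.35–0.8
  (against a structure-prior baseline of 0.152). Two effects cap the
  contrast: a spurious transition can join an existing small rate class at
  no dimension cost, and the sampled hyperprior adapts its scale to the
  data, which softens the Occam penalty on small spurious rates. A
  decision rule "MP(zero) > MP(positive) for every truly-zero transition"
  is therefore not reliably attainable at this data size, and typically
  9–10 of 12 transitions are classified correctly; the per-transition MPs
  themselves, not a hard threshold, are the meaningful output.
* Root-state recovery decays with the expected number of changes per path:
  at ~3 changes the root posterior under the *true* generator already
  spreads well below 0.5; at ~1 change (`root_informative`) the averaged
  ancestral vector concentrates (> 0.5, typically > 0.8) on the true root
  state. Conversely, on saturated symmetric data the averaged vector
  approaches the equivocal 0.25-per-state report.

## Diagnostics

Per chain: the log harmonic mean (lnHM) of sampled likelihoods, computed in
log space; chains are called converged when all pairwise |delta lnHM| < 1.
The harmonic mean is a convergence heuristic only — it is not used as a
marginal-likelihood estimate. Residual autocorrelation of the retained
log-likelihood trace is tested with the Ljung–Box portmanteau statistic
(lags default min(10, n/5); the scalar tested is the log-likelihood trace);
`autocorrelation_thin` doubles the thinning factor until the test stops
rejecting or a floor sample size is reached. The Ljung–Box implementation is
cross-checked against statsmodels to 1e-6.

## Numerical choices

* Likelihood underflow is prevented by per-edge rescaling with accumulated
  log scale factors; impossible data report -inf cleanly.
* Bell numbers use the Bell-triangle recurrence in exact integer arithmetic.
* Tie-breaks: class indices are canonicalised by first appearance in the
  fixed row-major transition order; model scores sort by posterior then
  signature; the top-set BF threshold is inclusive (BF = 2 is in).
* Degenerate inputs: empty matrices, non-overlapping tree/matrix pairs,
  constant diagnostic traces, and all-zero structures with a rate move drawn
  are all handled explicitly (error, error, error, null iteration).

## Known limitations

* No polymorphic or ambiguous tip states; one state per species.
* No covarion/hidden-rate models, no trait-dependent diversification, no
  extinction in the tree simulator.
* The harmonic-mean heuristic is insensitive to some convergence failures;
  no Gelman–Rubin/ESS suite is included.
* Marginal-likelihood-based model choice (stepping stone, path sampling) is
  out of scope; all model comparison is frequency-based over the RJ sample.
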