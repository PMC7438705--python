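# Methods

## Model

An examinee's latent state at occasion t is an attribute profile
α ∈ {0, 1}^K.  A prerequisite hierarchy is a DAG over attributes; its
reflexive transitive closure is the reachability matrix R, and a profile is
*permissible* when every mastered attribute has all of its R-prerequisites
mastered.  Profiles are indexed canonically: ascending mastery count, ties
by the vector read as a binary number with attribute 1 most significant
(000, 100, 110, 111 for the linear chain).

**Measurement.**  Each item has a logistic response function with intercept,
main effects, and interactions over the attributes it measures (LCDM).
Under a hierarchy some effect columns become linearly dependent over the
permissible space; the hierarchical variant (HDCM) fixes those at zero.  The
mask is derived constructively: candidate effect subsets are enumerated
prerequisite-closed-within-the-item first (size ascending, then
lexicographic), and a subset is kept iff its indicator column over the
permissible space is linearly independent of the intercept and the columns
already kept.  This reproduces the textbook nested parameterization for a
linear hierarchy — intercept, first main effect, then the chain of
higher-order interactions — keeps all 2^m − 1 effects for independent
attributes, and generalizes to arbitrary DAGs.  The free-effect count always
equals the number of distinct predictor values the item can realize, which
the test suite verifies exhaustively for K ≤ 4.  Item parameters are shared
across occasions so profiles keep the same meaning over time.

**Structure.**  The profile sequence is a first-order Markov chain: initial
prevalence δ (length C) and one C × C row-stochastic transition matrix per
adjacent occasion pair (a stationarity flag ties them).  Transitions are
parameterized directly as probabilities; the multinomial-logit form is a
conversion layer only, since the two are one-to-one for positive rows and
the probability form has a closed-form M-step.  An optional no-backsliding
constraint zeroes transitions to destinations not componentwise ≥ the
source; it is **off** by default in estimation — the fitted model may allow
regression even when the generator forbids it — because the modelling
convention for transition DCMs permits backsliding and neither choice is
forced by the theory.  Both behaviours are available behind a flag.

## Estimation

Marginal maximum likelihood via EM.

* **E-step**: scaled forward–backward over the C-state chain gives exact
  occasion marginals γ and adjacent-pair marginals ξ per examinee;
  per-occasion emission log-probabilities are max-shifted before
  exponentiation, so valid input never produces NaN.  The forward value of
  the likelihood is tested against brute-force enumeration of all C^T
  trajectories.
* **M-step**: δ and τ are posterior-weighted relative frequencies (masked
  cells pinned to zero, rows renormalized; an empty row falls back to a
  self-transition).  Item parameters maximize the weighted Bernoulli
  likelihood aggregated to the C profile covariate patterns, by L-BFGS-B
  with warm starts and capped iterations — a generalized EM step whose
  surrogate never decreases, preserving the monotone-likelihood guarantee
  checked by the tests.
* **Monotone items** (default on): all non-intercept effects are bounded
  below by zero, a sufficient condition for success probability to be
  nondecreasing along the mastery order.  A projection that merely clips
  after an unconstrained step could reduce the likelihood; bound-constrained
  maximization cannot.  The bound is stronger than monotonicity itself
  (negative interactions compensated by main effects are excluded); set
  `monotone=False` to lift it.
* **Separation**: if any coefficient exceeds 20 in absolute value the item
  is refit with an L2 penalty of 1e-4 and a warning.
* **Starts**: δ, τ rows ~ Dirichlet(1); intercepts ~ N(−1, 0.5²); effects
  ~ |N(1, 0.5²)|.  Each start runs a short burn-in (30 iterations by
  default); the best continues to convergence (relative log-likelihood
  change < 1e-6, cap 500 iterations).  Everything is driven by one seed.
* **Nesting**: `embed_htdcm` re-expresses an H-TDCM fit in the full 2^K
  space with identical likelihood; passing it as an extra start when
  fitting the TDCM guarantees the fitted TDCM log-likelihood is at least
  the hierarchical one, which makes the likelihood-ratio comparison
  well-ordered in finite samples.  The LRT uses the conventional chi-square
  reference; boundary effects from parameters pinned at zero are not
  corrected.

AIC/BIC are reported as conveniences beyond the LRT-based comparison.

## Q-matrix designs

The canonical designs encode their defining properties deterministically:
Q1 contains no R^T block (and, for independent attributes, never isolates
attribute 1); Q2 one R^T block plus one identity block (a single block when
R^T *is* the identity); Q3 two R^T blocks.  Remaining rows cycle through the
2^K − 1 nonzero q-vectors in canonical order, skipping rows that would
change the design's block count.  Because the rows of R^T are pairwise
distinct, the maximum number of disjoint R^T blocks equals the minimum
multiplicity of an R^T row in Q, which is counted exactly.  Users can supply
any Q-matrix by CSV instead.  Coverage below three items per attribute is a
warning, not an error: the three-item rule is an identifiability condition
for specific model families, not a structural impossibility.

## Synthetic data generator

The generator emulates a short formative-assessment panel: N = 1000
examinees, T = 3 occasions, 10 items on K = 3 attributes, initial profiles
uniform over the permissible space, and fixed item quality (intercept −1,
main effect 2, interaction 1 on every free term), so the success floor is
logit⁻¹(−1) ≈ 0.27 and the full-mastery ceiling at least logit⁻¹(1) ≈ 0.73.
The occasion-to-occasion law is a *learning kernel*: each unmastered
attribute whose prerequisites were mastered at the previous occasion is
gained independently with probability `p_gain` (default 0.4, chosen so that
mastery visibly accumulates over three occasions); mastery is never lost.
Replication r uses seed `base_seed + r`, and trajectories are shared across
Q-designs within a hierarchy at equal seeds, which pairs the design
comparisons.

What the generator does **not** emulate: forgetting or regression,
examinee-level covariates, item-parameter drift, missingness, polytomous
responses, and misspecified Q-matrices.  Passing classification-accuracy
tests therefore demonstrate recovery under a well-specified, monotone
learning process — not robustness to the messiness of real classroom data.
Because the kernel is a modelling choice (only the uniform initial
distribution is pinned down by the study design it follows), absolute
classification rates depend on it: a no-loss kernel concentrates later-time
prevalence near full mastery, and forward–backward smoothing pools
information across occasions, both of which push rates up relative to
benchmarks generated under other transition laws.  Comparative statements
across hierarchies are more transferable than absolute levels.

## Problem sizes

The bundled study runs use 20 replications per condition with N = 1000
(2-replication smoke configurations in the unit tests), reporting Monte
Carlo standard errors alongside every rate; the parameter-recovery check
uses a single N = 2000 fit.  The full 100-replication design is a
configuration change (`StudyConfig(n_reps=100)`), not a code change.

## Known limitations

* Complete dichotomous data only; missing responses raise an error.
* No standard errors or Wald inference on parameters; uncertainty is
  reported only as Monte Carlo SEs across replications.
* Profiles are anchored by the Q-matrix and monotone effects, so label
  switching is not handled beyond that anchoring.
* The hierarchy is taken as known; estimating it from data is out of scope.
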