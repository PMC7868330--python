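# Methods

## Model family

The package implements four diagnostic classification models as constrained
log-linear latent class models over the 2^A attribute profiles.  Each item
is represented internally by a class-by-parameter design matrix: the row
for class *c* maps the item's parameter vector to its kernel (log-odds of a
correct response) for that profile.  The saturated two-attribute LCDM has
columns (1, α₁, α₂, α₁α₂); C-RUM drops the interaction column; DINA keeps
(1, α₁α₂); DINO keeps (1, 1−(1−α₁)(1−α₂)).  Items requiring a single
attribute have the same two-column design under every submodel, so the four
parameterizations coincide there — a structural fact the tests exploit as
an estimation cross-check (all four fits must reach the same maximized
likelihood on a single-attribute-only test).

Only one- and two-attribute items are supported: every built-in design
requires at most two attributes per item, and three-way interaction terms
are out of scope.

Latent classes are enumerated with the last attribute varying fastest
([0,0,0], [0,0,1], …, [1,1,1]), matching the printed item-to-profile
convention, and class indices are the binary encoding of the profile with
attribute 1 as the most significant bit.

## Generating design

The built-in Q-matrices are balanced cycles: for three attributes, the six
patterns 100, 010, 001, 110, 101, 011 repeated; for five attributes, the
five singles followed by the seven pairs involving attribute 1 or 2,
repeated.  Shorter tests are leading truncations of the 36-item design, so
test-length effects are nested.  The mixed-model test assigns submodels by
item position in the cycle LCDM → DINA → DINO → C-RUM, giving equal counts
of each type on 12/24/36-item tests.

Generating parameter values are intercept −1.1, main effects 1.3,
e parameter 3, interaction 0.24.  On a two-attribute saturated item this
yields guessing 0.25 and full-mastery probability 0.85 — item
discrimination 0.60, a medium-quality item.  The increment for
single-attribute items is not uniquely pinned down by those four values; we
use 3 (logistic(−1.1+3) ≈ 0.87), the only choice consistent with the
0.85 − 0.25 quality anchor, and expose it as
`single_attribute_increment`.

## Population model

Attribute profiles are generated by dichotomizing a latent multivariate
normal with zero mean, unit variances and an exchangeable correlation
matrix (default ρ = 0.70, typical of correlated subdomains in large
educational surveys).  The threshold is the standard-normal quantile
leaving `base_rate` mass above it (τ = Φ⁻¹(1 − BR); 0.6745 for BR = 0.25).
Class proportions are therefore orthant probabilities of the latent normal,
not free parameters; for two attributes at BR = 0.5 the joint-mastery rate
has the closed form 1/4 + arcsin(ρ)/2π ≈ 0.3734, which the tests check.
Exchangeability requires ρ > −1/(A−1) for positive definiteness and is
validated at construction.

Responses are independent Bernoulli draws given the profile, with
probabilities from the item response functions.  All randomness flows
through numpy Generators; a replication is bit-reproducible from its seed.

## Estimation

Marginal maximum likelihood with a saturated structural model (free class
proportions), by EM:

* **E-step** on deduplicated response patterns (cost scales with distinct
  patterns, at most 2^k, rather than N).
* **Item M-step**: the expected complete-data Bernoulli log-likelihood is
  concave in the log-linear parameters; a damped Newton solver on the
  class-level design matrix maximizes it.  When the unconstrained optimum
  violates the order constraints (mains > 0, e > 0, interaction > −each
  main) the item is re-solved by SLSQP with the strict inequalities
  enforced at a margin ε = 1e−4 and |parameters| capped at 15 (keeping
  probabilities off exact 0/1).  The constraints anchor classes to
  profiles, so label switching cannot occur.
* **Structural M-step**: class proportions are weighted posterior means,
  floored at 1e−10 inside logarithms only (no class deletion).
* **Multi-start**: by default 20 random starts (intercepts ~ U(−2, 0),
  increments ~ U(0.5, 3), interactions ~ U(−0.5, 0.5), proportions
  ~ Dirichlet(1)) run 10 short iterations; the best 5 run to convergence
  (absolute log-likelihood change < 1e−6, max 1,000 iterations) and the
  highest final log-likelihood wins.  For large well-identified fits
  (N in the thousands) the likelihood is effectively unimodal under the
  anchored constraints, and the study loops use the reduced
  `LARGE_N_FIT_CONFIG` (4 starts, 2 survivors, 8 short iterations).

Classification defaults to the modal-posterior class profile (ties broken
to the lowest class index and flagged); marginal-EAP thresholding of
per-attribute posterior mastery probabilities at 0.5 is available as an
option.

## Evaluation

RMSE and bias for one parameter over R replications are
√(Σᵣ(λ−λ̂ᵣ)²/R) and Σᵣ(λ−λ̂ᵣ)/R — note bias is *true minus estimate*.
Condition summaries average the per-parameter values over items within each
family (intercept, main, e, interaction); non-converged replications are
excluded from the averages and reported in `n_converged`.  Classification
accuracy is the percentage of respondents whose whole estimated profile
matches the truth.  The tetrachoric estimator fixes thresholds at the
sample margins and solves the orthant-probability equation for ρ (capped at
±0.999 for boundary tables).  The factorial-ANOVA summary regresses each
condition-level outcome on all factor main effects and two-way interactions
(Type II sums of squares) and reports partial η² = SS_effect /
(SS_effect + SS_residual); factors degenerate for an outcome (e.g. the
model factor for interaction-parameter outcomes, which only mixed tests
produce) are dropped and reported as missing, and interaction terms are
dropped when they would exhaust the residual degrees of freedom.  ANOVA
outcomes use RMSE and absolute bias per family.

## Problem sizes

The full crossed design — 8 sample sizes × 3 test lengths × 2 attribute
counts × 2 base rates × 4 models = 384 conditions, 100 replications each —
is what the grid builder produces by default, but the shipped analyses run
reduced versions as the package's own desk-scale choices: 20 replications
for the headline recovery/classification conditions, 3–5 replications on
reduced grids for the rank and effect-size summaries.  Replication seeds
derive from (base seed, condition index, replication index) via
SeedSequence, so any slice of the grid reproduces identically regardless of
execution order or parallelism.

## What the simulator does and does not emulate

It emulates the study conditions: correlated dichotomized-normal
populations, the balanced Q-matrices, medium-quality items of a single
discrimination level, and correctly specified fitting (the generating model
is fitted, including known item types on mixed tests).  It does not emulate
Q-matrix misspecification, item-quality heterogeneity, polytomous
responses, slipping/guessing asymmetries beyond the log-linear form, or
model misfit — so passing tests show estimator correctness under the study
conditions, not robustness on real data.

## Known limitations and observed deviations

* At reduced replication counts the grid-average accuracy ranking places
  the mixed-model test within a couple of points of DINA (full-scale
  results separate them more cleanly); the rank test therefore allows a
  2.5-point Monte-Carlo slack.
* Robust (sandwich) standard errors and fit indices (AIC/BIC) are not
  computed; the fit result reports the log-likelihood and convergence
  diagnostics only.
* Very small samples (N = 50) with 32 classes rely heavily on the
  constrained fallback solver; estimates sit at bounds frequently, and the
  runner records rather than raises non-convergence, mirroring how
  unstable small-N fits are handled in practice.
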