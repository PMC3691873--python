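# Methods

## Model

An additive Bayesian network over variables X₁…X_V is a DAG together with
one generalised linear node model per variable: Gaussian with identity link
for continuous variables, Bernoulli with logit link for binary ones.  The
joint density factorises into the node conditionals, so the log marginal
likelihood (evidence) of a structure decomposes into per-(child, parent-set)
terms.  Arcs encode statistical dependency only; orientation is generally
not identifiable from observational data (likelihood equivalence), and no
causal reading is intended.

Binary variables must be coded 0/1 and enter designs uncentred, so
intercepts are baseline log odds.  Continuous variables are by default
centred and scaled to unit variance on input: this makes the diffuse
coefficient prior comparably diffuse across variables and stabilises the
Newton iterations.  Standardisation is a package choice (flag-controlled),
not a claim about how any particular published analysis prepared its data;
effects are then per-SD of the parent.

## Node evidence by Laplace approximation

Priors: coefficients iid Normal(0, 1000); Gaussian residual precision τ ~
Gamma(0.001, 0.001).  These are conventional diffuse choices; evidence
values (and hence selected structures) do depend on them, which is why they
are recorded in every score cache.

The Gaussian precision is treated as a parameter inside the approximation,
on the log scale (λ = log τ) so the mode is interior and the same machinery
serves both families.  The posterior mode is found by:

- Gaussian nodes: block ascent — β | λ is an exact ridge solve from the
  sufficient statistics (XᵀX, Xᵀy, yᵀy), λ | β is exact in closed form; the
  fixed point is the joint mode.  Because only sufficient statistics are
  needed, cache construction slices one precomputed XᵀX per child,
  independent of n.
- Bernoulli nodes: Newton–Raphson with step-halving from β = 0.

Convergence: max |gradient| < 1e−6, max 200 iterations; additionally, an
accepted step below 1e−9 with gradient below 1e−4 counts as converged
(near the mode the log posterior is flat to machine precision and halving
can otherwise stall one ulp short of the gradient tolerance).  The evidence
is log p(θ̂|D) + (d/2)·log 2π − ½·log det(−H).  Rank deficiency of the
design (perfectly collinear parents) is detected before fitting and recorded
as an invalid cache entry rather than a misleading score.

Accuracy, verified in the test suite against independent oracles: within
0.5 log units of the closed-form conjugate normal–gamma evidence (Gaussian,
n = 200) and of 2-D adaptive quadrature (Bernoulli, n = 100).  Under
quasi-separated binary data the Laplace error grows but remained within the
same bound on the tested draws.

## Exact structure search

Scores for all admissible (child, parent set) pairs are cached (parent sets
up to `max_parents`, minus banned arcs, plus retained arcs).  The globally
optimal DAG is found by best-sink dynamic programming: bestparents(child, C)
— the best score over parent sets drawn from candidate set C — is a
subset-max (zeta) transform of the cache, computed with vectorised bit-mask
passes; best(W) for every node subset W then follows from
best(W) = max over sinks s of bestparents(s, W∖{s}) + best(W∖{s}).
Complexity is O(V·2^V) beyond the transform, practical to ~20 variables
(the configurable `EXACT_SEARCH_LIMIT`); 17 variables with max-parents 4
takes well under a minute on one CPU, dominated by the ~43 000 Laplace fits
of the cache.  Ties are broken deterministically: smallest sink index in the
forward pass; fewest arcs, then lexicographically smallest parent set, at
reconstruction.

Setting a response restriction admits only arcs terminating at that node;
the optimum is then the best-subset GLM for the response plus parentless
other nodes, so multivariable regression selection is exactly the
restricted special case of the multivariate search, and its score can never
exceed the unrestricted optimum.

The hill climber (for larger V) applies the best single-arc
addition/deletion/reversal until no move improves, over seeded random
restarts (default 100; starting DAGs from a random topological order with
arc probability 2/V).  It is score-bounded by the exact optimum and in the
test suite matches it on small problems.

## Posterior effect summaries

For a chosen DAG each node is refitted and every parameter summarised by
its median and central 95% credible interval, computed deterministically:
the log posterior is evaluated on a 1024-point grid spanning ±6 marginal
SDs (from the inverse Hessian) along the ridge path — the remaining
parameters set to their conditional mode given the scanned value — then
normalised; quantiles come from the interpolated CDF.  For a quadratic log
posterior the ridge profile reproduces the Laplace marginal exactly.  A
pure conditional slice (others frozen at the mode) was rejected: its
curvature is the conditional precision H_jj rather than the marginal
1/(H⁻¹)_jj, which materially understates interval width whenever parameters
are correlated (e.g. intercept and a binary parent's slope) and visibly
undercovered in calibration runs.  The Gaussian precision is summarised on
the residual-SD scale (exp(−λ/2), interval endpoints flipped).

Because nodes are independent given the structure, a node's summaries
depend only on its own parent set — identical across any DAGs that share
it.  With diffuse priors the medians track maximum-likelihood estimates
(verified within 2 ML standard errors in the suite), and 95% intervals
cover true simulated coefficients at ~94–95%.

## Robustness

Parametric bootstrap: fit the chosen DAG's node models at their posterior
modes, simulate B replicate datasets of the same n by ancestral sampling,
re-run the same search on each, and keep only arcs recovered in ≥ threshold
of replicates (defaults B = 100, threshold 0.5).  Recovery is tallied
direction-blind (skeleton match) by default, since orientation is not
identifiable; a flag enables strict tallying.  Replicates are seeded
independently from the master seed, so results are reproducible regardless
of execution order; failed replicates are skipped and logged, with a hard
error beyond 10%.

Majority consensus: arcs appearing in strictly more than the threshold
fraction of input DAGs.  The result can be cyclic in pathological cases; it
is flagged with a suggested set of lowest-support feedback arcs, never
repaired silently.

## Synthetic data generator

`simulate` draws ancestrally from a fully specified network; it emulates
cross-sectional, complete-case study data — independent rows, exact GLM
conditionals — and deliberately not missingness, measurement error,
clustering or longitudinal structure, so passing tests speak to the
estimator under the model, not to those real-data complications.
`study_shape_spec` produces a randomised 17-variable network (5 binary, 12
continuous, ~17 arcs, max 4 parents) with slopes drawn from ±[0.3, 1.0] on
the standardized-parent scale, unit Gaussian precisions and zero intercepts
(binary prevalences near 50%) — the shape of a few-hundred-subject
questionnaire study.  Two fixed benchmarks are exported:
`six_node_benchmark_spec` (mixed families, moderate effects 0.5–0.9, used
for interval-calibration studies) and `five_node_strong_spec` (effects
≥ 1.0, used for bootstrap pruning studies, where an injected zero-effect
arc should be removed at threshold 0.5 while all true arcs survive).

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down sizes chosen to exercise each
property meaningfully on a desktop: brute-force search equivalence at V ≤ 4
(543 DAGs, full enumeration); scoring oracles at n = 100–200; coverage at
40–100 replicates of n = 500; bootstrap studies at B = 40 over 10–20 runs,
n = 300; structure-recovery trends over n ∈ {100, 400, 2000} on 8-node
networks, with a single full-scale 17-variable exact search at n = 400.
Score caches store 64-bit floats keyed by sorted parent tuples; the
cache-size estimate is capped (default 2·10⁶ entries) with a refusal
directing users to lower `max_parents`.

## Known limitations

Evidence values depend on the diffuse-prior hyperparameters; no prior
sensitivity analysis is automated.  Laplace accuracy degrades for small n
with near-separated binary nodes.  Only binary and Gaussian families are
supported (no categorical >2 levels, Poisson, or random effects); missing
data are handled by complete-case deletion only; the exact search is
exponential in V and refuses beyond its limit rather than degrading
gracefully.  A single optimal DAG is returned, not its likelihood-
equivalence class.
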