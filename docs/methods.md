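# Methods

This note records the statistical model behind `symptomnet`, the numerical
choices that affect results, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## Model

Observed data are an n x p matrix of integer symptom severities on the
0-10 numeric rating scale (0 = absent). The network model is a Gaussian
graphical model on a latent scale: conditional independence between two
symptoms given all others corresponds to a zero in the precision matrix K,
and the edge weight reported for a pair is the regularized partial
correlation w_ij = -k_ij / sqrt(k_ii k_jj).

Estimation follows the EBIC-glasso workflow standard in psychometric
network analysis:

1. **Input correlations.** Pairwise Spearman rank correlations with
   average ranks for ties. Spearman (not polychoric) is used because it is
   what the emulated analysis specifies; a polychoric input would be the
   natural extension point for heavily tied ordinal items. Sample rank
   correlation matrices are positive semidefinite in theory; as a guard
   against numerical violations the matrix is repaired by clipping
   eigenvalues at 1e-8 and rescaling to unit diagonal, and the repair is
   recorded on the result because it changes downstream numbers.
2. **Graphical lasso.** K maximizes
   log det K - tr(SK) - lambda * sum_{i!=j} |k_ij| (diagonal unpenalized),
   solved by block coordinate descent with incrementally maintained
   residuals (numba-compiled; a whole-path fit at p = 19 takes tens of
   milliseconds, which is what makes full re-estimation inside bootstrap
   loops affordable). Convergence: max |dW| < 1e-7 between sweeps, at most
   10,000 sweeps; non-convergence raises, carrying lambda and the last
   residual.
3. **Penalty path and selection.** 100 log-spaced penalties from
   lambda_max = max off-diagonal |s_ij| down to 0.01 * lambda_max, fit with
   warm starts; the penalty minimizing EBIC_gamma = -2L + E log n +
   4 E gamma log p (L = (n/2)[log det K - tr(SK)], E = edge count) is
   selected, gamma = 0.5 by default. Ties break toward the larger penalty
   (sparser model) — reproducible and conservative.

## The plain vs thresholded estimator

The default estimator returns the selected penalized fit as-is — the
behavior of the reference R implementation and evidently of the study this
package models (its reported strength centralities near 5.4 on 18 possible
edges imply a dense network). This default has a measurable weakness that
users should understand: when several strong edges are present, the
likelihood gain from relaxing the penalty (un-shrinking those strong
edges) outweighs the per-edge EBIC cost, so the selected model also admits
moderate spurious edges. On synthetic data with 15 true edges
(|partial| >= 0.2, p = 10, n = 2000) the plain estimator finds every true
edge but only ~45% of absent edges stay absent — and this persists on
continuous Gaussian data, so it is a property of path-based EBIC
selection, not of the ordinal discretization. The support-constrained MLE
of the oracle support has a clearly better EBIC than anything on the
lasso path; the path simply never visits it.

`estimate_network(..., edge_threshold="auto")` is the remedy, mirroring
the thresholded variant of the same estimator family: after selection,
edges with |w_ij| < log(p(p-1)/2) / sqrt(n) are pruned. Under the same
recovery conditions this attains 100% sensitivity and 100% specificity,
and it is the recommended configuration when the scientific question is
*which* conditional dependencies exist. The price is severity at small n:
at p = 19, n = 367 the cutoff is 0.27 (0.49 in subsamples dropped to
n = 110), which empties study-scale networks and destroys case-dropping
stability. Hence the package default remains the plain estimator for
study-scale descriptive use, with the threshold exposed as an explicit
choice (`RunConfig.edge_threshold`).

## Centrality

Strength and expected influence are the absolute and signed row sums of
the weight matrix. Closeness and betweenness need a weight-to-length map,
which the underlying definitions leave open; the package uses the
reference convention length = 1/|w| (strong edges are short). Closeness is
1 / sum of shortest-path distances to all other nodes, with the convention
closeness = 0 when any node is unreachable — sparse EBIC networks are
often disconnected, and this keeps the index well defined. Betweenness
uses fractional credit on tied shortest paths and counts each unordered
pair once (an ordered-pairs flag doubles it for cross-checks against the
other convention). Z-standardized columns use the sample SD over nodes.
Both closeness and betweenness are verified to 1e-9 against an exhaustive
simple-path enumerator on graphs with p <= 7.

## Bootstrap machinery

- **Edge accuracy:** B (default 1000) resamples of patients with
  replacement; the full estimation pipeline re-runs per resample;
  per-edge 95% percentile intervals. Resamples that produce a constant
  column are redrawn (bounded at 100 tries).
- **Difference tests:** two edges (or two nodes, on strength or expected
  influence) differ significantly when the percentile interval of their
  bootstrapped difference excludes zero at alpha = 0.05. No multiplicity
  correction by default, matching the reference procedure; a Bonferroni
  flag exists.
- **Case-dropping stability:** for each drop proportion q in a grid
  (default 0.05 to 0.75 by 0.05), B subsamples of floor(n(1-q)) patients
  without replacement; the product-moment correlation between full-sample
  and subsample centrality vectors is recorded (rank correlation by flag;
  a constant vector scores 0). The CS coefficient is the largest q at
  which >= 95% of subsamples reach correlation >= 0.7, required to hold
  at every smaller q as well.
- **Seeding:** every replicate draws its generator from a spawned seed
  sequence keyed by (root seed, grid position, replicate index), so runs
  are reproducible and replicates independent of execution order.

## Synthetic-data generator

A latent Gaussian copula: latent vectors are multivariate normal with the
correlation matrix implied by a known sparse precision matrix; each
coordinate is discretized through per-symptom thresholds. The zero
threshold is the standard-normal quantile of (1 - prevalence); conditional
on being symptomatic, categories 1-10 get probabilities proportional to
exp(tau * k), with tau fit by bisection (range +/-50, 200 iterations) so
the expected all-patient mean matches the target. The map from tau to the
conditional mean is strictly increasing with range (1, 10), so the fit is
unique; targets with conditional mean exactly 1 or 10 use the degenerate
distribution, and marginals with mean > 10 x prevalence or
mean < prevalence are rejected as infeasible (a symptomatic patient scores
at least 1).

Ground-truth networks place uniformly random edges with requested absolute
partial correlations; positive definiteness is enforced by shifting the
precision diagonal up to a 0.05 eigenvalue floor, which shrinks all
partials uniformly — the constructor rejects requests the shift would
shrink below half the requested minimum. The study-scale truth (p = 19)
encodes the qualitative structure reported for postoperative NSCLC
cohorts — strong pain-fatigue, pain-shortness-of-breath,
pain-disturbed-sleep, nausea-vomiting, distress-sadness ties over a 10%
random background — with marginals from the published cohort table. One
printed marginal (numbness: mean 0.95 at 7.36% prevalence) is infeasible
as an all-patient mean on a 0-10 scale (its maximum is 0.736); the
generator substitutes 0.095, consistent with the reported median of 0,
and warns.

What the generator does *not* emulate: per-symptom severity SDs and
medians (only prevalence and mean are calibrated — simulated SDs run
higher than the published ones because the temperature family has one free
parameter per symptom); item non-response and informative missingness;
demographic covariates; any departure from the latent-normal dependence
structure. Passing tests therefore show that the pipeline recovers
known latent structure under realistic zero-inflated ordinal marginals —
not that the published network itself is reproduced; without the raw
data, its exact edge weights, centralities, and the printed CS of 0.673
are not recoverable, though study-scale synthetic runs land in the same
qualitative regime (CS around 0.5-0.6, "good" stability, with strength
and expected influence agreeing).

## Descriptives and planning conventions

Severity statistics are computed over all patients, zeros included — the
only convention consistent with published rows like nausea (prevalence
20.4%, mean 0.23). Quartiles default to linear interpolation, with the
discrete nearest-order-statistic convention selectable, since
questionnaire reports rarely state one. Non-response inflation in the
sample-size planner is multiplicative, ceil(total x (1 + rate)), which
reproduces the published plan (190 -> 228 at 20%); the divisive
alternative ceil(total / (1 - rate)) = 238 is available by flag. The
response rate rounds to one decimal.

## Problem sizes in tests and the acceptance script

Monte-Carlo suites use 20 replicates for edge recovery (p = 10,
n = 2000), 5 study-scale cohorts (p = 19, n = 367) with B = 100
case-dropping replicates on a 0.1-0.7 grid and a 40-point penalty path,
and B = 100-500 for bootstrap checks — sizes at which the checked
quantities are stable to well within the asserted margins while the whole
suite runs in minutes on one CPU. Layout export uses deterministic
seeded Fruchterman-Reingold with |w| as attraction; figure rendering is
deliberately out of scope (numeric exports are the contract).

## Known limitations

- Spearman input treats ordinal ties crudely; population rank
  correlations of heavily zero-inflated items are attenuated relative to
  the latent correlations, which slightly biases edge weights toward zero
  (sign consistency is preserved and tested).
- EBIC selection over a single penalty path cannot separate weak true
  edges from moderate spurious ones (see the estimator discussion above).
- The CS coefficient depends on the drop grid; values are comparable only
  across runs with the same grid.
- No missing-data handling: incomplete score matrices are rejected.
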