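# Methods

## Problem setting

Early-stage bioprocess screening evaluates a coarse full-factorial grid of
conditions — here pH, load density (g L⁻¹) and conductivity (mS cm⁻¹) on a
4 × 3 × 4 lattice, run in duplicate — and scores each well on several
competing responses: %yield (maximize) and the HCP (ppm) and host-cell DNA
(ppb) impurity contents of the flowthrough pool (minimize). The package
implements a data-driven multi-objective optimization workflow on such
grids and a regression-based DoE baseline to compare it against.

Physical levels are replaced by consecutive integer codes 1..L per factor,
assigned in ascending order. All geometry downstream — simplex moves,
distances between optima — lives in this coded lattice, so units never mix.
Missing wells are imputed with *surrogates*: values one full admissible-band
width outside the band (below L for a maximized response, above U for a
minimized one), so their individual desirability is exactly 0 for every
weight and a search is steered away from unmeasured regions. Surrogate
flags are retained; surrogate-bearing conditions are excluded from Pareto
front membership by default because their values are fabricated, not
measured.

## Desirability amalgamation

Each response y_k is mapped to d_k ∈ [0,1] by the one-sided Derringer–Suich
transform: for maximization d_k = 1 above the target T_k, 0 below the lower
limit L_k, and ((y_k−L_k)/(T_k−L_k))^{w_k} inside the band; minimization
mirrors this with the upper limit U_k. The weight exponent w_k > 0 shapes
the curve (1 linear, <1 concave up, >1 concave down) and encodes the
importance of reaching the target. The total desirability is the geometric
mean D = (∏ d_k)^{1/K}, so one worthless response annihilates the score
and the argmax of D is always Pareto optimal.

With duplicated wells, D is computed per replicate and arithmetically
averaged (D̄). The alternative — average replicate responses first, then
one D — is available as `average="response"`; the two differ only under
weight curvature and the per-replicate average is the default.

Numerical conventions: band-edge equalities (y = T, L, U) are routed
through the power branch (the branches agree there; fixing one makes
results bit-stable); 0^w is defined as 0 for all w > 0 so the transform is
continuous at the band edge; zero-width bands (T = L or T = U) are
rejected at construction.

## Weights as search dimensions

Fixing the weights a priori requires expert knowledge that early screening
rarely has. Instead, each response's candidate weight levels (default 0.5,
1.0, 2.0) are coded 1..M like factor levels and appended to the lattice:
X (48 points, 3-D) expands to XW (1296 points, 6-D) whose objective D_T at
(x ++ w-codes) is the replicate-averaged desirability of condition x under
that weight set. The global scalar optimum xw* is the argmax of D_T —
jointly the best operating condition and weight set. Argmax ties are broken
by the lexicographically smallest coded tuple.

## Grid-compatible simplex search

A sequential Nelder–Mead-family search restricted to the lattice. The
initial simplex is the start point plus one +1 axis step per dimension
(flipped to −1 at the upper bound), i.e. n+1 distinct vertices — 7 in the
6-D XW space. Each iteration reflects the worst vertex through the centroid
of the rest, rounds half-away-from-zero to the nearest lattice point, and
clamps to the bounds; a reflection that fails to improve on the worst
vertex falls back to an inside contraction (midpoint of worst and
centroid), and failing that all non-best vertices shrink halfway toward the
best vertex. Every evaluation is cached: re-proposing a visited point costs
nothing, matching the experimental reality that a measured condition need
not be rerun. Efficiency is therefore counted two ways — unique lattice
points evaluated, and unique experimental conditions in X touched (the
projection that determines wet-lab cost; moves in weight dimensions only
are free).

Termination: `stall_limit` (default 3) consecutive iterations without a
newly evaluated point improving on the worst vertex, simplex collapse, or
`max_iterations` (default 200). Because rounding can collapse a unit-scale
simplex prematurely, a stalled or collapsed search polls the axis neighbors
of its best vertex and restarts from an improving neighbor (a standard
convergence safeguard in lattice direct search); a search thus terminates
only at a lattice-local optimum. On strictly unimodal separable objectives
every lattice-local optimum is global, which is why exhaustive-start
recovery tests demand — and get — 100%. On real multimodal landscapes the
poll changes nothing about basin structure; searches still end at local
optima. All moves and the poll are config switches on `SearchOptions`.

A terminus is classified *converged* when it equals xw*; *near-optimal*
when its X-projection belongs to the Pareto front (computed on replicate-
mean responses, surrogate conditions excluded) and its D_T is within 1% of
the value at xw*; otherwise *fail*. Worst-vertex value ties are broken by
the lexicographically smallest tuple; the reported best point breaks cached
maxima ties by earliest evaluation.

## Pareto analysis

Standard dominance: a condition dominates another when it is at least as
good in every goal-oriented response and strictly better in one.
Conditions with identical response vectors are both kept on the front. The
front implementation is a vectorized pairwise scan; tests verify it against
an independent early-exit O(n²) loop oracle on randomized instances
(n = 10–500). Trade-offs between responses are quantified by Spearman's ρ
on favorability-scaled values with the t-approximation p-value (n−2 df;
adequate at the 48-condition scale; a permutation option exists).

## DoE baseline

Per response, classical stepwise regression over all monomials of total
degree ≤ 4 in the centered coded factors (35 terms for 3 factors):
partial-F p-to-enter 0.05, p-to-remove 0.10, no hierarchy enforced.
Centering (coded integers minus their mean) tames collinearity among high
powers and leaves predictions unchanged. Candidate columns that are
linearly dependent on the current design (inevitable: a 3-level factor
supports only quadratic identifiable powers) are skipped with a warning.
Three initial structures are postulated — intercept-only, full quadratic,
full quartic — and the lowest-training-RMSE final model wins (ties: fewer
terms, then first listed). RMSE uses the n-denominator on the fitting data.
With an exact fit the partial-F test degenerates; p is set to 0 when a term
removes residual error and 1 when it cannot, so noiseless recovery is
well-defined. Models are fitted on raw replicate rows with missing wells
excluded, never on surrogates.

Predicted responses feed the same desirability transform, giving a
predicted table D̂_i per weight set. Two metrics compare prediction to
measurement: the Pearson correlation r_i between the measured and
predicted desirability vectors, and λ_i, the Euclidean distance in coded
units between measured and predicted argmax conditions (argmax ties
resolved lexicographically and flagged). A weight set passes the *lenient*
profile when r_i ≥ 0.6 and λ_i ≤ 2.0 (a face diagonal of the unit cube —
a follow-up study would still capture the optimum) and the *stringent*
profile when r_i ≥ 0.95 and λ_i ≤ 1.0; success rates are passing fractions
over the 27 sets. Stringent can never exceed lenient (nested regions).

## Synthetic case studies

No raw screening measurements are publicly deposited, so the generator
fabricates case-study-shaped data. Noiseless surfaces are logistic
squashes of low-order polynomials in the normalized factor codes: yield
rises with conductivity and load (weak product binding at high salt,
displacement at high load); HCP content also rises with conductivity
(anionic impurities stop binding) with a weak load effect; DNA content
adds a pH × conductivity interaction. This builds in the screening
trade-off — favorability-scaled yield is negatively rank-correlated with
scaled impurity clearance (ρ ≈ −0.9 yield/HCP, ≈ −0.57 yield/DNA on the
default surfaces) — and, being logistic, defeats quadratic models while
remaining smooth.

Defaults define the study conditions: the 4 × 3 × 4 grid in duplicate
(48 conditions), weight levels 0.5/1.0/2.0 per response, additive Gaussian
noise on yield (sd 2.5 percentage points, ≈5% CV), multiplicative
lognormal noise on the impurity contents (σ = 0.05), and 5% of
(condition, impurity) wells dropped as missing — impurity assays, not
yield, fail in practice. Yield is truncated to [0, 100]%. Desirability
targets default to the best noiseless grid value and limits to the worst
(a `margin` option widens the band to keep all desirabilities strictly
positive where a property requires it). Everything is driven by one
`numpy` generator seed; identical seeds give byte-identical tables.

A ground-truth bundle (noiseless surfaces, brute-force Pareto set,
per-weight-set argmaxes, xw*) accompanies every case so each downstream
stage can be checked for exact recovery in the noise-free limit. What the
generator does **not** emulate: real assay error structure (ELISA
plate-position effects, detection-limit censoring), resin-lot variability,
and the sharper cliff-like trends of some real multimodal resins — passing
tests show the machinery is correct on data of this shape, not that any
particular resin behaves this way.

## Evaluation harness

The benchmark protocol deploys the search from 300 random starting points
(sampled without replacement when the lattice is large enough), classifies
every terminus, and reports percentages. Efficiency curves give, per
budget b of unique X conditions and threshold t ∈ {95%, 99%} of max(D_T),
the fraction of searches whose best-so-far within b conditions reaches
t · max(D_T); fractions are non-decreasing in b and the 99% curve never
exceeds the 95% curve. The normalized-D_T histogram (percent of maximum
over all XW points, with the fractions within 1% and 5% of the maximum)
quantifies how sharply peaked a landscape is. All studies are reproducible
bit-for-bit under a fixed seed.

Problem sizes used throughout the test and acceptance runs are the default
study conditions themselves: 48-condition grids, 1296-point expanded
lattices, 300-start studies, and exhaustive all-start sweeps on 48- and
1296-point unimodal lattices — each completing in seconds.

## Known limitations

- The one-sided desirability transform only; two-sided (target-is-best)
  responses are out of scope.
- Weights live on the user's coded grid; no continuous weight optimization.
- The precise move set of the original gridded simplex variant is not
  published; the policy here (reflection → inside contraction → shrink →
  stall poll, no expansion step) is this package's own reconstruction, with
  every rule switchable.
- Stepwise regression is deliberately the classical partial-F procedure —
  no cross-validation, information criteria or shrinkage — because the
  baseline exists to reproduce standard DoE practice, not to improve it.
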