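# Methods

## Model

`nichescreen` fits a presence–background maximum-entropy niche model: the
Gibbs distribution p(x) ∝ exp(λ·f(x)) over the background sample, with λ
chosen to maximize

    (1/m) Σ_presence λ·f(x_i) − log Σ_background exp(λ·f(x_b)) − Σ_j β_j |λ_j|.

This is the convex dual of constrained entropy maximization: with the
penalty at zero, the fitted distribution's expected feature values equal
the presence sample means exactly (the moment-matching property the test
suite checks by brute-force expectation).

**Features.** Raw predictors are min–max scaled to [0,1] on the combined
presence+background training sample (making the fit invariant to affine
rescaling of inputs) and expanded into classes: linear, quadratic, product
(all unordered pairs), hinge (forward and reverse, knots equally spaced —
default 50 per variable) and threshold (step functions, default 50 knots).
Prediction clamps inputs to the training range. Default classes are LQHP
with regularization multiplier (RM) 1.0, the conventional automatic choice
above 80 presence samples.

**Penalties.** β_j = RM × b_class(m) × max(sd_j, floor)/√m, where
b_class(m) interpolates the published class base-penalty tables in the
presence count m (L/Q: 1.0→0.05 between m=10 and 100; P: 2.6→0.05;
H: 0.5; T: 2.0→1.0), sd_j is the feature's presence-sample standard
deviation, and the floor is 1/√m for hinge/threshold features (guarding
near-constant steps) and 10⁻⁶ otherwise. The tables live in
`ModelSettings.beta_tables` and are overridable; no claim is made of
bit-identity with any particular historical implementation.

**Optimization.** λ is split into positive and negative parts, turning the
L1 term into a smooth bound-constrained objective solved by L-BFGS-B from
a zero start — exact, deterministic (the `seed` argument is reserved for
stochastic initializations), tolerance 10⁻⁷, coefficients below 10⁻¹⁰
zeroed. Constant feature columns are dropped with a warning; exceeding the
iteration cap raises a convergence error carrying the optimizer
diagnostics.

**Outputs.** Raw output is normalized to sum 1 over the training
background (checked to 10⁻⁹). Logistic output is τ·c·raw/((1−τ) + τ·c·raw)
with c = e^H (H = entropy of the fitted raw distribution) and τ = 0.5,
which reduces to c·raw/(1+c·raw); the no-information model maps to 0.5
everywhere. Complementary log-log output is not implemented.

## Screening ensemble

A sprint is `runs_per_sprint` (default 10) independent runs; an ensemble
is `n_sprints` (default 100) sprints. Each run draws `k_per_run` *distinct*
variables uniformly from the pool — without replacement within a run, so
that with k×runs draws the mean per-variable use count is exactly
k×runs/n — fits a model on that subset, and computes permutation
importance normalized to sum 100 over the subset. The tally table
accumulates use counts and importance; average importance ranks variables,
ties broken by pool order. Sprint-end checkpoint models are fitted on the
current top-k; while fewer than top-k variables have been used, selection
is deferred and no checkpoint is fitted, keeping sprint metrics comparable.

Per-run seeds derive from `SeedSequence([master_seed, run_index])`
(sprint-end model seeds are offset by 2³¹), so results are identical under
any worker count or execution order; tally updates are applied in
run-index order. Failed runs are logged and excluded from the tally. An
experimental early-stopping rule (off by default) halts once the top-k set
has been unchanged for a configurable number of consecutive sprints.

**Stability.** The stability sprint is the smallest index from which the
top-k (as a set, or as an ordered list) never changes through the final
sprint; if the selection still changed at the final sprint it is reported
as undefined rather than trivially equal to the last index.

## Evaluation statistics

- **AUC**: rank-based (Mann–Whitney), ties counting ½.
- **Permutation importance**: each variable's values permuted jointly
  across the stacked presence+background rows, training-AUC drop from
  baseline floored at 0, single permutation by default (configurable),
  drops normalized to percentages. Training-data convention; variables
  absent from the model score 0, and the vector sums to 100 whenever any
  drop is positive.
- **AICc** = 2K − 2lnL + 2K(K+1)/(n−K−1), K = nonzero coefficients, lnL the
  sum of log raw outputs renormalized over the evaluation extent (presence
  plus background rows when supplied; presence-only otherwise, documented
  on the function). Undefined (NaN with warning) when n ≤ K+1 — with
  50-knot hinge features and small presence samples this happens routinely
  and is reported, not hidden.
- **Niche overlap**: maps normalized to sum 1 over shared valid cells;
  D = 1 − ½Σ|p1−p2|, I = 1 − ½Σ(√p1−√p2)². Both statistics are computed on
  whatever surface is supplied (the CLI uses logistic maps); an I ≥ D
  ordering is not asserted anywhere, only the [0,1] bounds and symmetry.
- **Collinearity**: pairwise Pearson r/r² and VIF_j = 1/(1−R²_j) with
  intercept, flags at r > 0.8, r² > 0.8, VIF > 10. Perfectly collinear
  columns report VIF = ∞ rather than being dropped — the report describes
  the pool, it does not prune it.

## Occurrence handling

Exact-coordinate duplicates are removed keeping the first. Thinning is a
greedy keep-first pass in record order: a record is kept iff its haversine
distance (Earth radius 6371 km) to every previously kept record is at
least the buffer radius (default 16 km). Greedy keep-first is
deterministic and auditable, and the retained set provably satisfies the
minimum-separation property, but the retained *count* depends on input
order — order-independent thinning variants would return different counts
from the same data.

## Synthetic study systems

The generator emulates the structure screening sees in real use: a stack
of spatially smooth, cross-correlated continuous layers; a true
suitability surface driven by a known subset; presences sampled
proportionally to suitability. Layers are white noise smoothed by a
Gaussian kernel (σ = `smoothness` cells), standardized and linearly mixed
through the Cholesky factor of the target correlation (AR(1) structure
ρ^|i−j| when a scalar ρ is given — a rough analogue of the redundancy in
bioclimatic stacks; exactness is asymptotic in grid size). Suitability is
the inverse-logit of the stated linear(+quadratic) combination of
standardized true layers. Presences are distinct cells drawn with
probability proportional to suitability (exponential-key weighted sampling
without replacement), at cell centres, optionally jittered.

Default scenario: 60×60 grid, 12 independent layers, smoothness 2 cells,
three true variables with equal-magnitude standardized coefficients
(+3, −3, +3 — a strong effect, roughly 20-fold odds per standard
deviation), 150 presences. These defaults define the "strong 3-signal"
system used by the recovery tests and the acceptance script.

The benchmark deliberately uses *independent* layers and a short
correlation length, for two reasons rooted in how tally screening works.
First, under predictor redundancy the "true top-k" label is ill-posed at
small subset size: a variable correlated with an absent true driver
legitimately carries its signal within a run, monopolizes runs its
counterpart is missing from, and can out-average a true variable whose
importance is diluted by splitting the per-run 100% with co-occurring true
variables — so recovery under strong redundancy measures proxy-swapping,
not screening quality. Second, because every run's importances are
normalized to 100 regardless of model quality, runs containing no true
variable still award the full 100 points; on long-correlation-length
landscapes a noise layer that happens to align spatially with the presence
cluster wins those runs consistently and accumulates a high average. Both
effects are properties of the method itself (the pairwise k=2 regime is
the worst case), are worth knowing about when interpreting screening
output on real, strongly collinear stacks, and motivate keeping k_per_run
a substantial fraction of the pool.

What the generator does *not* emulate: derivation of bioclim-style layers
from monthly climatologies, non-Gaussian or anisotropic spatial structure,
sampling bias in occurrences, and observation error. Recovery results on
these scenarios therefore demonstrate the screening mechanism under known
ground truth, not performance on any particular real data set.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down experiments chosen as
the smallest sizes at which each property is meaningfully exercised: most
unit tests use a 40×40, 6-layer scenario with 80 presences and 400
background points; the recovery experiment uses the default strong
scenario with k=4 per run, 30 sprints × 10 runs (100 samples per
variable, above the ≈80 floor below which selection becomes unreliable),
1000 background points and 20 master seeds; screening fits there use 8
hinge knots, which preserves the LQHP model family at a fraction of the
50-knot design-matrix width. Accounting and draw-frequency checks that
need no fitting run the full 100-sprint × 10-run shape in draw-only mode.

Raster I/O supports the ESRI ASCII grid format; inputs must be
pre-aligned (no reprojection or resampling), categorical layers are not
supported, and background sampling is uniform without replacement over
valid cells — exhaustive when n equals the number of valid cells.

## Known limitations

- Thinning reproduces the buffer criterion, not any specific historical
  tool's ordering; counts from real data sets are order-dependent.
- The penalty tables are configurable defaults, not a bit-exact clone of
  any MaxEnt release; AICc values are comparable within this package, not
  across implementations.
- Permutation importance with a single permutation is noisy for weak
  effects; raise `n_permutations` when ranking closely matched variables.
- With heavy feature classes and few presences, K can exceed n−1 and AICc
  is undefined by construction; the checkpoint log then carries NaN.
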