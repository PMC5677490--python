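# Methods

This note documents the models, conventions and numerical choices behind
`mustelimb`, in the order data flow through the pipeline.

## Trees and regime paintings

Trees are rooted, strictly binary and ultrametric, with branch lengths in
millions of years (My). Ages run backwards from the present: extant tips sit
at age 0 and the root at the tree height. Ultrametricity is checked with a
tolerance *relative* to tree height (1e-6 × height) because published dated
trees carry rounded branch lengths. Polytomies are rejected by default; an
opt-in resolver breaks them with 1e-8 My edges, which the relative tolerance
absorbs. All position arithmetic on branches uses a rootward-origin,
half-open convention: a position *p* ∈ [0, 1) on an edge lies `p·length`
below the edge's parent end.

Taxon grafting attaches an extant tip on the stem of a named sister tip or
clade at a stated divergence age; the pendant edge length equals the
divergence age, so the result is ultrametric by construction and grafting
followed by pruning restores the original tree.

A *regime painting* assigns a selective regime to every point of every
branch as ordered (regime, duration) segments per edge. Segment durations
must sum to the edge length, adjacent segments must differ, and each edge
must begin in the regime in force at its parent's end. When a painting is
built from node states alone (no sampled change points), a parent→child
regime transition is placed at the edge midpoint — a deterministic,
symmetric default. Stochastic character mappings carry their own sampled
change points and never use this rule.

## Trait preparation

The measurement schema is 14 linear forelimb dimensions (mm): scapula
length; humerus length, AP and ML mid-shaft diameters, deltoid ridge length,
epicondylar breadth; radius length, AP and ML diameters; ulna length, AP and
ML diameters, olecranon process length; metacarpal III length. Specimen
tables are averaged per species on the raw mm scale first; logs are taken
afterwards (means, then regressions on logs).

Size correction regresses each log trait on the log geometric mean of all 14
traits across species (OLS with intercept) and keeps the residuals. Natural
logarithms are used throughout; the log base only rescales residuals
uniformly and cancels from every downstream proportion. The PCA decomposes
the *covariance* matrix of the residual columns — they are already
dimensionless log deviations on a common scale — with a correlation-mode
flag for sensitivity checks. No phylogenetic correction is applied to the
PCA: this is a deliberate property of the workflow being implemented, and
its known consequence (ordinary PCA on phylogenetically correlated data can
separate clades without any adaptive shift) is demonstrated explicitly in
the test suite's null-scenario contrast.

Loading signs are fixed deterministically (the largest-magnitude loading of
each component is made positive) so output is identical across linear
algebra backends. Component significance uses the broken-stick rule with a
*strict* exceedance; a non-contiguous significant set is reported as-is with
a warning rather than truncated.

## Trait-diversification models

All six models are Gaussian at the tips of an ultrametric tree. With shared
time `t_ij` (root-to-MRCA duration) and patristic distance `d_ij`:

- **BM1** — `E[x] = x₀`, `Cov = σ² t_ij`; parameters (σ², x₀), k = 2.
- **BMS** — as BM1 with `Cov_ij = Σ_r σ²_r · (time the shared path spends in
  regime r)`; k = 1 + m for m regimes.
- **OU1 / OUM** — `Cov_ij = σ²/(2α) · e^{−α d_ij} (1 − e^{−2α t_ij})`, the
  stationary form for ultrametric trees; tip expectations are Hansen weights
  of the optima along each root-to-tip lineage with the root placed at the
  root-regime optimum. OU1: k = 3 (α, σ², θ); OUM: k = 2 + m (α, σ², m
  optima). α and σ² are shared across regimes; only θ shifts. An opt-in flag
  estimates the root state separately (meaningful only for OUM; for OU1 on
  an ultrametric tree the root and optimum columns are collinear).
- **EB** — BM whose rate decays as `σ² e^{r t}` with r ≤ 0:
  `Cov_ij = σ² (e^{r t_ij} − 1)/r`, reducing exactly to BM1 at r = 0; k = 3.
- **WN** — iid Normal tips, no tree; k = 2.

These parameter counts reconcile the published AICc bookkeeping at n = 40:
−99.7 from lnL 52.0 (k = 2), −97.9 from 52.3 (k = 3), −60.7 from 32.5
(k = 2), and k = 2 + regimes for the unconstrained rows (−124.8 from 68.3 at
k = 5 exactly; −114.657 from 61.9 at k = 4, one rounding unit from the
printed −114.6). The multirate-BM row is not reproducible from its printed
lnL under any natural k and is left unreconciled.

**Fitting.** Every model's mean parameters are linear and its covariance
scale multiplicative, so the fits profile them analytically: GLS for the
root/optima, the MLE `quad/n` for the scale, leaving at most one nonlinear
parameter (α for OU, the rate for EB) or the m − 1 rate ratios of BMS. The
nonlinear parameter is searched on a log-scale grid (α ∈ [1e-6, 50/height];
α is weakly identified on 40-tip trees, so bounds scale with the tree)
followed by bounded polish of *each grid-local minimum* — likelihoods of
discrete and OU models can hide a narrow interior optimum next to a flat
large-parameter plateau, and refining only the single best grid point was
observed to miss it. BMS uses multistart L-BFGS on the log rate ratios.
BM1, WN and the 2-tip cherry reduce to closed forms and are tested against
them. Shared-time, distance and MRCA matrices are computed once per tree and
cached; fits are pure functions of (tree, painting, data).

`n` for AICc is the number of tips with data. Phylogenetic half-life is
reported as `t½ = ln2/α` for OU fits; BM has no finite half-life and the
table prints a dash rather than a number.

## Stochastic character mapping

Locomotor habit is a 4-state Markov chain; the default Mk structure is
equal-rates (one free parameter, uniform root prior), with all-rates-
different available by flag. Histories are sampled by (i) joint ancestral
state draws from the Felsenstein pruning partials and (ii) endpoint-
conditioned path sampling along every edge — Nielsen-style rejection with a
forced first jump when the endpoints differ, falling back to uniformization
after 100 failed attempts. Both samplers are validated against a quadrature
oracle for the conditional expected number of changes. Multi-regime fits are
repeated per mapping and the parameters arithmetically averaged; mappings
whose fit fails to converge are excluded from the averages and counted, not
imputed. The production default is 500 mappings; tests use 10–100 with fixed
seeds.

## Unconstrained shift detection

The reversible-jump sampler explores OU models whose optimum θ changes at an
unknown set of shift points (≤ 1 per branch, position uniform along the
branch), with α and σ² shared. Priors: truncated Poisson (mean λ = 1, max
n/2) on the shift count with shift branches uniform among subsets;
half-Cauchy on α (scale 1 My⁻¹) and on √σ² (scale = 1 data SD); optima
Normal(data mean, 2 × data SD). Moves: birth 0.2, death 0.2, slide 0.1, α
0.15, σ² 0.15, θ 0.2. Because births draw the new optimum from its prior and
the position uniformly, the Green acceptance ratio collapses to
`L-ratio × λ/(k+1) × p_death/p_birth`; this cancellation is verified by
prior-only chains recovering the truncated-Poisson count prior at λ ∈
{0.5, 2}. The covariance depends only on (α, σ²), so its Cholesky factor is
cached across the mean-only moves that dominate the chain.

Per-branch posterior shift probabilities are sample fractions over the
thinned post-burn-in states; branches at or above the 0.20 threshold are
frozen into a painting (shift at the posterior-mean position, descendants
inherit the new regime until a nested significant shift) whose
posterior-mean α, σ² and optima parameterise the "converted" model entered
into the AICc table with k = 2 + regimes. Production chains run 1,500,000
iterations; tests and the CLI default use 20,000 with burn-in 0.3 and
thinning 10. At that length, independent chains on borderline datasets can
disagree about near-threshold shifts; the recovery tests therefore measure
performance across many seeded chains rather than asserting any single
chain's output.

## Model adequacy

The phylogenetic Monte-Carlo test simulates data under the fitted null
(single-rate BM) and under the fitted best model, refits both models to
every simulated dataset, and forms two 95% *percentile* intervals of the
likelihood-ratio statistic `2(lnL_alt − lnL_null)` — percentile rather than
BCa, matching the plain "95% confidence interval" of the source workflow.
The observed LR is then located relative to both intervals
(consistent-with-null / consistent-with-best / outside-both). Refits reuse
the fitting machinery with a lighter grid (3 restarts); failed refits are
dropped and counted, with more than 5% failures an error. The production
iteration count is 10,000; tests use 200–500. Calibration: over 40 outer
replicates of BM-generated data, the observed LR falls inside the null CI
97.5% of the time at 500 iterations (nominal 95%).

## Synthetic data

The generator emulates the study design at known truth:

- **Tree** — pure-birth, default 40 tips rescaled to height 16 My (the
  simulator stops at the n-th speciation, so every pendant edge is extended
  by the exponential waiting time to the unrealised next event before
  rescaling). Pure birth rather than birth–death: the simplest ultrametric
  generator, since no test depends on topology realism.
- **Habits** — 4-state equal-rates Mk simulated root-to-tip, default rate
  0.02 My⁻¹ per pair (≈ a dozen transitions tree-wide, enough homoplasy for
  mapping to be non-trivial); redrawn up to 20 times if all tips coincide.
- **Traits** — log trait = intercept + slope × (BM size factor) + OU
  deviation. Intercepts are logs of realistic mid-sized mustelid dimensions
  (lengths ~20–65 mm, diameters ~4–5 mm); slopes deviate mildly from
  isometry (0.90–1.10); the size factor is BM with σ² = 0.02 My⁻¹ (log-scale
  SD ≈ 0.57 at the tips, a weasel-to-otter span). Deviations are OU with
  α = 0.26 My⁻¹ and stationary SD 0.08 log units, independent across traits.
- **Scenarios** — `A`: one optimum shift at the midpoint of the stem of the
  clade whose size is closest to 20% of the tips, with per-trait contrast
  2 stationary SD along a fixed gracility trade-off pattern (±1 on the 12
  informative traits, 0 on scapula length and humeral ML diameter). This
  yields a dominant first axis (PC1 ≈ 35% of variance on average) that
  separates the shifted clade, the structure the scenario exists to emulate.
  `B`: optimum shifts at 40% of the two longest terminal branches with
  opposite 6-SD contrasts along a radius-cross-section/manus pattern —
  6 SD because only ≈half the contrast is expressed at the tip at these α
  and branch lengths, and the scenario's target is a taxon that is the
  extreme score of its axis. `NULL`: single-regime BM deviations of matching
  tip variance, no shift.
- **Specimens** — 1–6 per species (uniform), log-normal measurement error
  with CV 0.05, typical of osteometric replicates.

The ground-truth record stores every generating parameter, the shifted
branches (as tip-label sets) and the latent species-level log trait table,
so any derived quantity can be recomputed from the seed.

What passing tests on these data do *not* show: robustness to real
measurement covariance between traits (deviations are generated
independently per trait), to non-ultrametric or misdated trees, to missing
specimens/traits, or to habit-dependent diversification rates — none of
which the generator emulates.

## Problem sizes and determinism

Tests run the study conditions at scaled sizes chosen as sensible
Monte-Carlo designs: 200 replicates for parameter recovery, 20 chains of
20,000 iterations for shift recovery, 40 × 500 iterations for adequacy
calibration, 50 mappings × 20 datasets for mapping invariants. Every random
component takes an explicit integer seed (numpy `default_rng`); identical
seeds give bit-identical trees, datasets, mappings, chains and bootstrap
vectors. The CLI fans a single master seed into per-stage seeds by fixed
offsets so stages are individually reproducible.

## Known limitations

- Univariate fits of PC scores, not a multivariate trait model (a property
  of the workflow, kept deliberately).
- θ-only shifts in the reversible-jump model; no shifts in α or σ², no
  parallel tempering, no marginal-likelihood estimation.
- OU covariances use the stationary ultrametric form; fossil (non-extant)
  tips are out of scope.
- Short (20k-iteration) chains can disagree on near-threshold shifts;
  production-length chains are the 1.5M-iteration default.
- The Mk fit assumes the habit evolves independently of the traits; no
  hidden-rate or joint estimation.
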