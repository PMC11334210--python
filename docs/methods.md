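# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `karyorate`, and what the simulation-based tests do and do
not establish.

## Model and likelihood

Chromosome-number evolution is modelled as a continuous-time Markov chain on
the product space of haploid count k ∈ [k_min, k_max] and a binary
hyperstate h (small/large range). Moves are single-step fusions (rate δ_h)
and fissions (γ_h), optional polyploidy (k → 2k, rate ρ_h, zero by default —
whole-genome duplication is undocumented in the mammalian clades this
toolkit targets), and hyperstate flips (q_SL, q_LS). States are indexed
count-major, hyperstate-minor; boundary moves that would leave the space get
rate zero and the diagonal closes each row.

**State-space bounds.** The observed counts determine the space: one step of
head-room beyond the observed range on each side (floored at 1), overridable
in config. This is the smallest space in which boundary species can both
gain and lose chromosomes; widening further changes likelihoods well below
estimation noise while growing the quadratic-cost generator.

**Likelihood.** Felsenstein pruning over the product space with per-node
rescaling. Tips are observed exactly (probability 1 on their (k, h) pair).
Two root treatments are provided: `obs_weighted` (default; FitzJohn-style
weighting of root states by their own partial likelihoods) and `flat`.
Polytomies are handled natively.

**Propagators.** Branch transition probabilities use an eigendecomposition
of the generator (cached per Q, applied as two matrix-vector products per
branch, inner loop compiled with numba). A scaling-and-squaring `expm`
fallback catches defective generators; routes agree to < 1e-10. For
*marginal ancestral-state reconstruction* transition matrices are instead
computed by **uniformization** (a nonnegative series with no cancellation):
reconstructions must rank states whose reachability requires many count
steps, and such probabilities (often < 1e-20) are pure roundoff under any
dense exponential, while uniformization preserves their relative accuracy.
The MCMC keeps the fast eigen route, where the likelihood is dominated by
resolvable states.

**Ties.** The "most probable ancestral count" breaks ties toward the lower
count, making tip rates deterministic.

## Bayesian fitting

Each free rate gets an independent exponential prior with rate 2 (mean 0.5
per unit tree height) — "biologically realistic" in the sense that expected
rates of karyotype change per unit of tree depth are well below 1. The
phrase "shape parameter" for a one-parameter exponential is read as the rate
parameter; a mean parameterisation is available.

Sampling is univariate slice sampling (step-out/shrink, default width 1, 20
step-out budget) sweeping all six rates; one generation = one sweep. Chains
initialise from uniform(0, 10) draws (re-drawn up to 20 times if the
posterior is non-finite). Per tree, several replicate chains run from
distinct seeds and the replicate with the highest final-generation log
posterior is kept — insurance against chains stuck on flat or multi-modal
likelihood surfaces. Post-burnin samples pool across trees; per-tree
original heights convert unit-height rates to per-MY rates.

Replication-mode defaults (500 generations, burnin 450, 6 replicates) are
short by general MCMC standards; the package warns and accepts longer runs.
Slice sampling needs no tuning runs but its draws are autocorrelated (lag-1
≈ 0.5 on these posteriors); distributional tests therefore thin chains
before i.i.d.-based comparisons such as Kolmogorov–Smirnov. Seeds derive
deterministically from a master seed via `SeedSequence([master, tree,
replicate])`; identical inputs give bit-identical chains.

## ΔR and HPD

ΔR_x = x_small − x_large per pooled posterior sample, on the per-MY scale.
The 95% HPD is the shortest window over sorted samples containing
⌈0.95 n⌉ points (the standard coda-style estimator). Support calls: HPD
entirely positive → small-elevated; entirely negative → large-elevated;
otherwise indeterminate. ΔR for q_SL vs q_LS is computed as a diagnostic
only.

## Tip rates

Marginal reconstruction uses the pooled posterior-mean rates on the
unit-height tree (the scale they were estimated on); the hyperstate is
marginalised out before taking the modal ancestral count; the rate divides
the absolute count difference by the branch length in MY. Zero-length
terminal branches with a count change yield an undefined rate, reported as
missing with a warning.

## Branch rate-bin scan

Every branch receives one of 21 multiplicative scalars spanning 0.5–2
(spacing 0.075; the grid does not contain 1.0 exactly, and the root
pseudo-branch is pinned to the nearest bin, scalar 1.025; an explicit-1.0
grid variant is available). A preorder scan evaluates, for each branch, the
parent's bin and its two neighbours; the candidate scalar multiplies the
branch length *and its not-yet-visited subtree's* (descendants are
re-decided at their own turn), and the full-tree log-likelihood under the
fixed pooled posterior-mean generator decides. Ties keep the parent's bin.

Two properties motivated the subtree-inheritance rule: the candidate set
always contains the current configuration, so the full-tree log-likelihood
is non-decreasing over the scan and the final configuration is never worse
than leaving every branch at the root bin; and inheritance is the natural
meaning of rate autocorrelation during a preorder walk. The scan is a
*greedy local* optimizer: on tiny instances where the constrained global
argmax can be enumerated it attains the optimum in most but not all cases
(measured ~70–80% of random 4-tip datasets on a 2-point grid). Exact global
search is exponential in branch count and the likelihood does not decompose
over branches, so no efficient exact algorithm exists for this objective.

Null behaviour worth knowing: on rate-homogeneous data, branches that happen
to carry no character change always gain likelihood from shrinking, so
assignments drift; whole trees drift coherently (up or down) while the grand
mean scalar across replicate datasets stays near 1. Interpretation should
therefore rest on *contrasts* between clades within a tree — as the
per-family elevated/depressed summaries do — not on absolute bin values.
Families need ≥ 5 taxa to be summarised; clade = all branches inside the
MRCA subtree of the family's tips (stem excluded), averaged across trees.

## Range size

Per species, duplicate coordinates are dropped, longitudes unwrapped when
the point set spans the antimeridian, the planar lon/lat convex hull taken,
and the hull polygon's area evaluated on a sphere of authalic radius
6371.0088 km via Girard's theorem (sum of interior angles). Fewer than three
non-collinear points give area 0. Classes split at the dataset median with
area ≥ median classed "large". The convex hull is one of several estimators
in use for occurrence data; it overestimates fragmented ranges and is
sensitive to outlying records (no spatial thinning is applied — hull area is
duplication-invariant anyway).

## Synthetic data

The generator emulates the target study design: ~110-tip ultrametric
birth–death trees (general sampling approach, so pendant branches are never
zero-length; stem dropped), unit-height rescaling, root haploid count 19
(the inferred ancestral carnivoran count), root hyperstate Bernoulli(0.5),
binary traits flipping symmetrically at rate 2 on unit-height trees.
Character histories are simulated *exactly* (Gillespie waiting times) with
the same move set the likelihood uses, counts floored at 1 and deliberately
uncapped — the fitted model's k_max is an inference approximation, not a
biological truth. Every simulation records its full event log; replaying the
log reproduces tip states exactly.

What the simulations do not emulate: non-ultrametric trees, topological
error, missing or mis-scored karyotypes, intraspecific count variation
(e.g. Robertsonian polymorphisms), and any correlation between the binary
trait and diversification. Passing tests therefore validate the inference
machinery under the model, not robustness to those real-data features.

**Experiment sizes** (the package's own choices, fixed by power analysis
before running):

- *Recovery*: 20 datasets on 150-tip unit-height trees with (δ_S, γ_S) =
  1.5, (δ_L, γ_L) = 0.25, q = 2; chains of 250 generations (burnin 150, 2
  replicates). A dataset "detects" elevation when at least one of
  ΔR_fusion/ΔR_fission has an entirely positive 95% HPD and neither is
  entirely negative. Long-chain checks showed each single process's ΔR is
  genuinely wide at this design (fusion/fission attribution along uncertain
  ancestral trajectories trades off), so per-process exclusion rates sit
  near 50–60% even though the rate *ordering* is recovered almost always.
- *Null calibration*: 50 replicates on 150-tip trees with state-independent
  rates δ = γ = 0.25 (the recovery design's low-rate value) and neutral
  traits at rate 2; the across-replicate sd of the posterior-mean ΔR is
  ≈ 0.17, so the grand mean resolves a ±0.05 band with ~2σ margin.
- *Planted clades*: 80-tip trees with one 12–30-tip clade simulated at twice
  the background rate (implemented as doubled branch lengths), scanned
  against the homogeneous generator.

## Known limitations

- The product-space model ignores diversification: if the binary trait
  affects speciation/extinction, rate estimates can be confounded (the
  false-positive experiment quantifies part of this risk).
- Single-tree datasets at desk scale often resolve the fusion *or* the
  fission contrast, not both; pooled multi-tree studies sharpen both.
- The rate-bin scan is greedy and its absolute scalars drift on
  signal-free data; use clade contrasts.
- Range-size classes inherit all biases of occurrence data (sampling
  effort, georeferencing errors); only coordinate-bounds filtering is
  built in.
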