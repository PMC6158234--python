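# Methods

## Model

`valleycross` simulates a constant-size Moran process with three
evolutionary stages S₀ → S₁ → S₂ and per-division stochastic fitness
effects. Per elementary step: one reproducer is sampled with probability
proportional to absolute fitness; a death target is sampled uniformly from
the *other* N−1 individuals (the reproducer never replaces itself); the
mother's two daughters — one in the mother's slot, one in the dead
individual's slot — share the mother's post-division effect buffer,
including the single new effect drawn at this division. The daughter in the
dead individual's slot is the one eligible to advance a stage (probability
u₁ for S₀ mothers, u₂ for S₁; no back mutation). Which daughter is
eligible is an arbitrary convention; the per-reproduction stage-advance
probability is u either way. The process stops at final-stage fixation or
after T_max elementary steps. The initial population is N stage-S₀
individuals with empty buffers (optionally seeded with `init_s1`
intermediate-stage individuals for benchmark scenarios).

Absolute fitness is `w = r_j · ∏ m_k` over the active effects
(multiplicative scale, default) or `w = max(ε, r_j + Σ(m_k − 1))`
(additive scale, `ε = 1e-9`). The multiplicative scale keeps the relative
effect of a stage mutation constant as absolute fitness drifts; the
additive scale is retained for robustness checks.

### Effect distributions

All four families are parameterized to mean 1 and variance V:

| family    | parameterization |
|-----------|------------------|
| log-normal | σ² = ln(1+V), μ = −σ²/2 |
| gamma      | shape 1/V, scale V |
| Laplace    | location 1, scale √(V/2) |
| centered Bernoulli | mass ½ on 1−√V and ½ on 1+√V |

The Bernoulli pmf is defined on offsets k = ±√V around the multiplicative
neutral point 1 (m = 1 + k): the only reading consistent with mean-1
multiplicative effects. "Exponential" in informal usage maps to the
Laplace (double-exponential) family. Draws ≤ ε are clamped to ε = 1e-9
(relevant only for Laplace at large V); fitness must stay positive for
proportional selection. V = 0 degenerates to a point mass at 1 for every
family.

### Effect lifetimes

*Deterministic* (default): each effect persists through exactly τ
divisions of the carrying lineage, counting the acquiring division; the
buffer is FIFO with capacity τ. τ=1 therefore means no inheritance and the
steady-state fitness distribution of a neutral population equals F exactly.
*Geometric*: each reproduction adds a Poisson(mean 1) number of separate
effect events; at each subsequent division of the lineage every
pre-existing event reverts independently with probability 1/τ (minimum
lifetime one division, mean lifetime τ). *Permanent* (τ=∞): effects fold
into a single running accumulator.

## Standard parameters

N=100, log-normal F with V=1e-4, τ=100, u₁=1e-4, u₂=2e-4, r₀=1, r₁=0.95,
r₂=5, T_max=3650·N elementary steps (3650 generations — a tumorigenesis-
scale horizon at ~1 division/day). These are the package defaults and the
conditions under which the headline crossing/tunneling comparisons are
made. τ=100 is the default persistence used for the standard valley
scenario; steady-state comparisons against single-cell data conventionally
use τ=10, within the biologically plausible 3–20 generation range.

## Estimators

* **Fixation probability**: fraction of replicates with final-stage
  fixation before T_max; 95% Wilson score intervals (the interval method is
  a package choice).
* **Tunneling probability**: a replicate "tunneled" if S₂ fixed and S₁
  never reached frequency N strictly before S₂ fixation; the estimator is
  the joint proportion over the fixation proportion. Replicates where S₁
  fixes and S₂ later fixes count as sequential fixation.
* **Conditional fixation by birth fitness**: every de-novo stage-advance
  birth is recorded with its relative fitness, defined as the mutant's w
  divided by the population mean w at that step (the population mean is the
  natural reference for "relative fitness within the extant population";
  computed just after the birth, including the mutant). A birth "founded
  the fixing lineage" if its clone identifier is present in the population
  at the moment of S₂ fixation (identifiers propagate to descendants;
  S₂ clones inherit their founding S₁ identifier). The curve is
  P̂(fitness|success)·P̂(success)/P̂(fitness) with Gaussian KDEs (Silverman
  bandwidth), clipped to [0,1] and reported only where the denominator
  density exceeds 1% of its maximum (support guard against ratio blow-up in
  the tails).
* **Steady-state samples**: populations with u₁=u₂=0 are snapshotted after
  burn-in of max(10τ, 100) generations; pooled values are normalized by the
  replicate mean by default (comparable across drifted replicates), or
  taken raw (`normalize="none"`), which preserves atomic distributions such
  as the centered Bernoulli exactly and is used for the τ=1 ≡ F identity
  check.
* **Variance calibration**: `calibrate_effect_variance` bisects V against
  the simulated steady-state variance with a fixed replicate budget and
  seed schedule (deterministic bracketing function), to a default 10%
  relative tolerance — used for comparisons across τ at equal standing
  variance.
* **Design bound**: the worst-case SE of a proportion from n events is
  0.5/√n (0.0158 for n=1000).

## Single-cell comparison

Fitness is taken inversely proportional to interdivision time (IDT) and
rescaled to mean 1. Interdivision times for PC9-like cells are modelled as
exponentially modified Gaussians (EMG = Normal(μ,σ²) + Exp(mean λ);
moments μ+λ and σ²+λ²); EMG parameters are user inputs, not fitted here.
The experimental sample is affinely standardized to the simulated sample's
(population-moment) mean and variance, and the integrated squared density
difference is estimated by leave-one-out Gaussian KDE:

MSÊ = (1/n)Σᵢ ĝ₋ᵢ(Xᵢ) + ∫ĥ² − (2/n)Σᵢ ĥ(Xᵢ),
z = MSÊ / (ΣᵢΣⱼ K²((Xᵢ−Xⱼ)/h))^{1/2}, two-tailed normal p.

∫ĥ² is computed in closed form from pairwise Gaussian convolution
identities (two kernels integrate to a √2·h kernel); numerical quadrature
is retained as a test oracle. The bandwidth is Silverman's rule on the
simulated sample, shared by both KDEs (one h appears in the statistic).
The i=j terms are included in the denominator's double sum.

**Calibration caveat.** With this normalization the statistic is strongly
conservative: under the null, z has sd ~1e-4–1e-3 (not 1) and p ≈ 1; even a
3-SD location shift yields |z| < 0.01. The test therefore detects only
gross discrepancies, and its z values should be read on that scale (matched
distributions: |z| ≲ 1e-3). The test suite checks the estimator against a
brute-force oracle, the null's centering and conservatism, and *relative*
power (a gross shift inflates |z| by >10×); it does not assert N(0,1)
calibration, which this normalization does not deliver. The z statistic
scales as 1/a under a joint affine rescale x→ax+b of both samples; the
accept/reject decision is unaffected.

## Synthetic lineage fixtures

`generate_lineages` builds complete binary lineage trees (default 30
founders × 7 generations, echoing typical time-lapse experiment scale)
with the chosen marginal IDT model. Sister correlation is induced by a
Gaussian copula: sisters share a latent Gaussian factor with loading √ρ,
and latents map onto IDTs through the marginal quantile function. This
keeps the marginal exactly as specified (so KS self-consistency holds)
while the sister Pearson correlation tracks ρ closely (within ±0.05 at
ρ=0.8 for the EMG marginal). An optional heritable multiplicative speed
factor with lifetime `heritability_tau` reuses the effect-buffer mechanism
and couples IDTs across generations; with it enabled the marginal is no
longer exactly the named model. The fixtures capture per-generation IDT
variability, sister correlation and optional persistence; they do not model
mother–daughter asymmetry, cell death, or circadian/confluence trends, so
passing the round-trip tests says nothing about those features of real
data.

## Numerical and implementation choices

* The inner loop is a numba-compiled kernel (~0.25 µs per elementary
  step at N=100, τ=100). Per-individual cached log-background sums are
  updated incrementally and fully re-summed once per τ divisions
  (ring-buffer wrap), bounding floating-point drift to ≤ τ incremental
  updates (~1e-13 relative) between re-syncs.
* Reproducibility: per-replicate child seeds derive from the master seed
  via `numpy.random.SeedSequence`; identical config + master seed give
  bit-identical outputs. The geometric-lifetime buffer has capacity
  τ + 10√τ + 20 (stationary active-event count is ~Poisson(τ); overflow
  probability negligible, and overflowing events would be dropped newest-
  first).
* Replicates stop early in provably absorbing stage configurations (e.g.
  u₁=0 with no mutants left) when no traces/snapshots are requested.
* EMG quantiles use monotone interpolation of the CDF on an 8192-point
  grid (~1e-4 absolute accuracy); scipy's generic numeric inversion is
  orders of magnitude slower.
* Problem sizes in the test suite: 2000 replicates per condition for the
  crossing/tunneling comparisons (worst-case proportion SE ≈ 0.011), 10⁴
  replicates for the classical-Moran benchmark, 10⁴ pooled cells for
  distribution identities, 10 replicates for the divergence slope test —
  the package's chosen trade-off between Monte-Carlo resolution and suite
  runtime; the CLI reproduces any of these at larger scale.

## Known limitations

* Exactly two mutational steps; no back mutation, recombination, spatial
  structure, or fluctuating N.
* The non-valley benchmark parameterization (`enforce_valley=False`) skips
  the r₂ > r₀ > r₁ ordering check; the config-file interface always
  enforces it.
* The goodness-of-fit z-test, implemented with the normalization above, is
  a conservative screen rather than a calibrated test (see caveat).
* Mutant-birth records are capped generously (≥10× the expected count);
  the de-novo birth *counter* is exact regardless.
* `conditional_fixation_by_fitness` flags every founder clone present at
  fixation; in rare replicates more than one S₁ clone coexists at S₂
  fixation and all are counted as successful.
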