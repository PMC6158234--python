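# valleycross

Stochastic simulation of **fitness-valley crossing in asexual populations
with heritable, finite-lifetime non-genetic fitness variation**, plus the
estimators and statistical tests needed to analyze it.

Populations of isogenic cells show substantial cell-to-cell fitness
variation (visible as variable single-cell interdivision times) that is
partially heritable over a handful of generations — an epigenetic, not
genetic, phenomenon. `valleycross` asks how such variation changes the
population's ability to cross a *fitness valley*: acquiring an advantageous
trait that requires passing through a deleterious intermediate mutation.
It is aimed at researchers in evolutionary dynamics and cancer biology who
want a fast, reproducible re-implementation of this model with a clean
Python API and CLI.

## The model

A modified Moran process with constant population size *N*. Individuals
occupy evolutionary stages S₀ → S₁ → S₂ with stage fitness multipliers
r₂ > r₀ > r₁ > 0 (deleterious intermediate, advantageous final stage; r₀ = 1).
Each elementary step one individual reproduces with probability
proportional to its fitness and another, chosen uniformly at random among
the rest, dies. The mutation S₀→S₁ (S₁→S₂) happens with probability u₁
(u₂) per reproduction in one daughter; there is no back mutation. One
generation is *N* elementary steps.

On top of the stage multiplier, every reproduction draws a multiplicative
fitness effect mₖ from a distribution *F* with mean 1 and variance *V*
(log-normal, gamma, Laplace, or centered Bernoulli), shared by both
daughters. Each effect persists through exactly τ divisions of the
carrying lineage, so an individual's absolute fitness after its *i*-th
reproduction is

    w_i = r_j · ∏_{k=i−τ+1}^{i} m_k .

τ = 1 means no inheritance of fitness effects (the steady-state fitness
distribution is *F* itself); τ = ∞ means permanent effects (mean fitness
diverges under selection). A geometric-lifetime variant (Poisson(1) effect
events per reproduction, each reverting with probability 1/τ per division)
and an additive fitness scale are also implemented.

The package computes: valley-crossing (final-stage fixation) probability
within a time horizon, the conditional *stochastic tunneling* probability
P(S₁ never fixed | S₂ fixed), the Bayes-rule curve
P(fix final stage | mutant birth fitness), steady-state fitness
distributions, and a kernel-MSE goodness-of-fit z-test comparing simulated
fitness distributions against single-cell-derived ones (fitness = 1/IDT).
A synthetic lineage-tree generator with tunable sister-cell IDT correlation
stands in for single-cell time-lapse datasets.

## Worked example

```python
from valleycross import (SimConfig, EffectDistribution, run_ensemble,
                         summarize, fixation_probability, tunneling_probability)

for tau in (1, 100):
    cfg = SimConfig(N=100, tau=tau,
                    effect_dist=EffectDistribution("lognormal", 1e-4))
    summ = summarize(run_ensemble(cfg, 200, master_seed=2))
    fix = fixation_probability(summ)
    tun = tunneling_probability(summ)
    print(tau, fix.estimate, tun.estimate)
```

Running `python examples/02_valley_crossing.py` (the same computation with
formatting) prints:

```
tau=  1: P(cross valley in 3650 gen) = 0.140 [0.099, 0.195];  P(tunnel | crossed) = 0.93 [0.77, 0.98] (n_fixed=28)
tau=100: P(cross valley in 3650 gen) = 0.145 [0.103, 0.200];  P(tunnel | crossed) = 0.66 [0.47, 0.80] (n_fixed=29)
```

Brackets are 95% Wilson confidence intervals. At 200 replicates the drop
in the tunneling fraction under persistent variation (τ=100) is already
resolved: a larger share of crossings happen by the deleterious
intermediate stage *fixing* first, because occasional high-fitness
intermediates drift to fixation instead of waiting for a rare double
mutant. The increase in the crossing probability itself is smaller than
the CI width here; at 2000 replicates per condition (the acceptance
suite's scale) the τ=100 crossing probability (~0.19) separates cleanly
from τ=1 (~0.11).

The other scripts in `examples/` each demonstrate one capability:
steady-state fitness distributions vs τ, the conditional-fixation curve,
the single-cell goodness-of-fit pipeline, and a shell sweep via the
`valleycross` CLI (subcommands `simulate`, `sweep`, `estimate`, `gof-test`,
`fixtures`, `report`).

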