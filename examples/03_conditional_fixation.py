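"""Which intermediate mutants found the lineage that eventually fixes?

Every de-novo intermediate-stage birth is recorded with its relative fitness
(mutant fitness over the population mean at that step).  Bayes' rule turns
the density of successful birth fitnesses into P(fix final stage | birth
fitness).  With persistent effects (large tau), mutants born fitter than
average are disproportionately likely to found the fixing lineage.
"""

import numpy as np

from valleycross import (
    EffectDistribution,
    SimConfig,
    conditional_fixation_by_fitness,
    run_ensemble,
)

cfg = SimConfig(N=100, tau=100, effect_dist=EffectDistribution("lognormal", 1e-4))
res = run_ensemble(cfg, 400, master_seed=3)
records = [m for r in res for m in r.mutant_births if m.stage_created == 1]
n_succ = sum(m.founded_fixing_lineage for m in records)
print(f"{len(records)} de-novo intermediate births, {n_succ} founded a fixing lineage")

curve = conditional_fixation_by_fitness(records)
print(f"overall P(found fixing lineage) = {curve.p_fix_overall:.4f}\n")
print("birth fitness (rel.)   P(fix | fitness)")
ok = np.where(curve.supported)[0]
for i in ok[:: max(1, len(ok) // 10)]:
    print(f"  {curve.grid[i]:>8.4f}            {curve.p_fix[i]:.4f}")

print(
    "\nThe curve rises with birth fitness: an intermediate born into a\n"
    "high-fitness background keeps that advantage for ~tau divisions,\n"
    "long enough to escape early stochastic loss."
)
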