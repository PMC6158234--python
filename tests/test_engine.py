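"""Moran valley engine: structural semantics and statistical equivalences."""

import math

import numpy as np
import pytest

from valleycross.effects import ConfigurationError, EffectBuffer, EffectDistribution
from valleycross.engine import (
    Individual,
    SimConfig,
    ValleyParams,
    additive_fitness,
    elementary_step,
    results_table,
    run_ensemble,
    run_simulation,
)


def _neutral_cfg(**kw):
    kw.setdefault("valley", ValleyParams(u1=0.0, u2=0.0))
    kw.setdefault("effect_dist", EffectDistribution("lognormal", 0.0))
    return SimConfig(**kw)


class TestValidation:
    def test_valley_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            ValleyParams(r0=1.0, r1=1.2, r2=5.0)
        with pytest.raises(ConfigurationError):
            ValleyParams(r1=-0.5)
        with pytest.raises(ConfigurationError):
            ValleyParams(u1=1.5)
        # escape hatch for non-valley benchmarks still requires positivity
        ValleyParams(r1=1.5, enforce_valley=False)
        with pytest.raises(ConfigurationError):
            ValleyParams(r1=-1.0, enforce_valley=False)

    def test_config_bounds(self):
        with pytest.raises(ConfigurationError):
            SimConfig(N=1)
        with pytest.raises(ConfigurationError):
            SimConfig(tau=0)
        with pytest.raises(ConfigurationError):
            SimConfig(scale_mode="log")
        assert SimConfig(N=50).steps == 3650 * 50


class TestElementaryStep:
    def test_neutral_zero_variance_step(self, rng):
        pop = [Individual() for _ in range(2)]
        cfg = _neutral_cfg(N=2)
        elementary_step(pop, cfg, rng)
        assert len(pop) == 2
        assert all(p.stage == 0 for p in pop)
        assert all(p.fitness(cfg.valley) == cfg.valley.r0 for p in pop)

    def test_certain_mutation_creates_one_s1_daughter(self, rng):
        pop = [Individual() for _ in range(4)]
        cfg = SimConfig(
            N=4,
            effect_dist=EffectDistribution("lognormal", 0.0),
            valley=ValleyParams(u1=1.0, u2=0.0),
        )
        ev = elementary_step(pop, cfg, rng)
        assert ev["mutation"] == 1
        stages = [p.stage for p in pop]
        assert stages.count(1) == 1
        mutant = pop[ev["death"]]
        assert mutant.fitness(cfg.valley) == pytest.approx(0.95)

    def test_daughters_share_new_draw_fifo(self, rng):
        """Hand-computed: tau=2, mother buffer [1.1], drawn m=0.9 -> both
        daughters carry [1.1, 0.9] with background 0.99."""
        pop = [
            Individual(buffer=EffectBuffer(tau=2, effects=[1.1])),
            Individual(buffer=EffectBuffer(tau=2, effects=[1.1])),
        ]
        cfg = _neutral_cfg(N=2, tau=2, effect_dist=EffectDistribution("lognormal", 1e-4))
        ev = elementary_step(pop, cfg, rng, forced_effect=0.9)
        mother = pop[ev["reproducer"]]
        daughter = pop[ev["death"]]
        for cell in (mother, daughter):
            assert cell.buffer.effects == [1.1, 0.9]
            assert cell.buffer.background() == pytest.approx(0.99)

    def test_population_size_conserved(self, rng):
        pop = [Individual() for _ in range(7)]
        cfg = SimConfig(N=7, effect_dist=EffectDistribution("lognormal", 1e-2), tau=3)
        for _ in range(50):
            elementary_step(pop, cfg, rng)
        assert len(pop) == 7


class TestRunSimulation:
    def test_no_mutational_input_means_no_fixation(self):
        cfg = _neutral_cfg(N=20, t_max=5000, seed=3)
        r = run_simulation(cfg)
        assert not r.s2_fixed and not r.s1_fixed
        assert r.n_s1_births == 0 and len(r.mutant_births) == 0

    def test_stage_counts_sum_to_N_throughout(self):
        cfg = SimConfig(N=30, t_max=30 * 200, trace_stride=30, seed=5, tau=5,
                        effect_dist=EffectDistribution("lognormal", 1e-3))
        r = run_simulation(cfg)
        t = r.trace
        assert ((t.n_s0 + t.n_s1 + t.n_s2) == 30).all()

    def test_s2_fixation_time_within_bounds(self):
        # strong benefit + certain mutations: fixation happens fast
        cfg = SimConfig(
            N=10,
            effect_dist=EffectDistribution("lognormal", 0.0),
            valley=ValleyParams(r1=0.99, r2=50.0, u1=0.05, u2=0.05),
            t_max=10 * 2000,
            seed=11,
        )
        r = run_simulation(cfg)
        assert r.s2_fixed and 1 <= r.s2_fix_step <= cfg.steps
        assert r.n_s1_births >= 1

    def test_moran_closed_form_small(self):
        """Single S1 mutant, V=0, no mutation: fixation frequency matches the
        classical Moran probability (1-1/r)/(1-1/r^N) (small-n smoke check;
        the full benchmark runs in the acceptance suite)."""
        N, r = 20, 0.9
        cfg = SimConfig(
            N=N,
            effect_dist=EffectDistribution("lognormal", 0.0),
            valley=ValleyParams(r1=r, u1=0.0, u2=0.0),
            init_s1=1,
            seed=2,
        )
        res = run_ensemble(cfg, 2000, master_seed=2)
        phat = np.mean([x.s1_fixed for x in res])
        p = (1 - 1 / r) / (1 - 1 / r**N)
        se = math.sqrt(p * (1 - p) / len(res))
        assert abs(phat - p) < 4 * se


class TestEnsemble:
    def test_reproducible_bitwise(self):
        cfg = SimConfig(N=20, t_max=20 * 300, seed=9, tau=3,
                        effect_dist=EffectDistribution("lognormal", 1e-3),
                        valley=ValleyParams(u1=5e-3, u2=5e-3))
        a = results_table(run_ensemble(cfg, 3, master_seed=123))
        b = results_table(run_ensemble(cfg, 3, master_seed=123))
        assert a.equals(b)

    def test_singleton_matches_run_simulation(self):
        cfg = SimConfig(N=10, t_max=500, seed=4)
        from valleycross.engine import child_seeds

        single = run_ensemble(cfg, 1, master_seed=4)[0]
        direct = run_simulation(cfg, seed=int(child_seeds(4, 1)[0]))
        assert single.n_steps == direct.n_steps
        assert single.s2_fixed == direct.s2_fixed
        assert single.n_s1_births == direct.n_s1_births

    def test_nreps_validation(self):
        with pytest.raises(ConfigurationError):
            run_ensemble(SimConfig(), 0)


class TestAdditiveScale:
    def test_additive_fitness_examples(self):
        assert additive_fitness(1.0, EffectBuffer(tau=5)) == 1.0
        buf = EffectBuffer(tau=5, effects=[1.02, 0.95])
        assert additive_fitness(1.0, buf) == pytest.approx(0.97)
        # large negative offsets clamp rather than go non-positive
        bad = EffectBuffer(tau=5, effects=[0.1, 0.1, 0.1])
        assert additive_fitness(0.5, bad) > 0

    def test_additive_engine_runs(self):
        cfg = SimConfig(N=20, t_max=20 * 100, scale_mode="additive", tau=5,
                        effect_dist=EffectDistribution("lognormal", 1e-3),
                        trace_stride=20, seed=8)
        r = run_simulation(cfg)
        assert (r.trace.mean_w > 0).all()


class TestGeometricLifetime:
    def test_runs_and_fluctuates(self):
        cfg = SimConfig(N=30, tau=5, lifetime_mode="geometric", t_max=30 * 500,
                        effect_dist=EffectDistribution("lognormal", 1e-3),
                        valley=ValleyParams(u1=0.0, u2=0.0), trace_stride=30,
                        seed=13)
        r = run_simulation(cfg)
        w = r.trace.mean_w.to_numpy()
        assert np.all(np.isfinite(w)) and np.all(w > 0)
        # variance in mean fitness indicates active effect turnover
        assert w.std() > 0

    def test_geometric_steady_state_variance_near_tau_times_V(self):
        """With Poisson(1) arrivals and geometric mean lifetime tau, the
        stationary number of active effects is ~tau, so the log-fitness
        variance is near tau*V for small V (order-of-magnitude check)."""
        V, tau = 1e-4, 5
        cfg = SimConfig(N=100, tau=tau, lifetime_mode="geometric",
                        effect_dist=EffectDistribution("lognormal", V),
                        valley=ValleyParams(u1=0.0, u2=0.0),
                        t_max=100 * 220, snapshot_generations=(200,), seed=21)
        res = run_ensemble(cfg, 100, master_seed=21)
        from valleycross.estimators import steady_state_sample

        _, _, var = steady_state_sample(res, 200)
        assert 0.3 * tau * V < var < 3.0 * tau * V


def test_infinite_tau_mean_fitness_grows():
    cfg = SimConfig(N=100, tau=math.inf, t_max=100 * 800, trace_stride=100,
                    effect_dist=EffectDistribution("lognormal", 1e-3),
                    valley=ValleyParams(u1=0.0, u2=0.0), seed=6)
    r = run_simulation(cfg)
    w = r.trace.mean_w.to_numpy()
    assert w[-1] > w[0]
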