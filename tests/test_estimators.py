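"""Ensemble summary estimators: proportions, Bayes curve, calibration."""

import numpy as np
import pytest

from valleycross.effects import EffectDistribution
from valleycross.engine import MutantRecord, SimConfig, ValleyParams, run_ensemble
from valleycross.estimators import (
    EnsembleSummary,
    EstimationError,
    calibrate_effect_variance,
    conditional_fixation_by_fitness,
    fixation_probability,
    proportion_se_bound,
    steady_state_sample,
    summarize,
    tunneling_probability,
)


def _summary(n_reps, n_fix, n_joint):
    s2 = (True,) * n_fix + (False,) * (n_reps - n_fix)
    tun = (True,) * n_joint + (False,) * (n_reps - n_joint)
    return EnsembleSummary(n_reps, n_fix, n_joint, n_fix - n_joint, s2, tun)


class TestProportions:
    def test_fixation_point_estimates(self):
        assert fixation_probability(_summary(100, 0, 0)).estimate == 0.0
        assert fixation_probability(_summary(50, 50, 10)).estimate == 1.0

    def test_wilson_interval_500_of_1000(self):
        est = fixation_probability(_summary(1000, 500, 0))
        assert est.estimate == 0.5
        assert est.ci_low == pytest.approx(0.469, abs=0.001)
        assert est.ci_high == pytest.approx(0.531, abs=0.001)

    def test_tunneling_ratio(self):
        est = tunneling_probability(_summary(1000, 300, 180))
        assert est.estimate == pytest.approx(0.6)

    def test_pure_sequential_fixation_gives_zero(self):
        assert tunneling_probability(_summary(100, 40, 0)).estimate == 0.0

    def test_zero_fixations_signalled(self):
        with pytest.raises(EstimationError):
            tunneling_probability(_summary(100, 0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSummary(10, 12, 0, 0, (), ())


class TestSeBound:
    @pytest.mark.parametrize(
        "n,expected", [(1000, 0.015811), (4, 0.25), (10**6, 5e-4)]
    )
    def test_values(self, n, expected):
        assert proportion_se_bound(n) == pytest.approx(expected, rel=1e-3)

    def test_domain(self):
        with pytest.raises(ValueError):
            proportion_se_bound(0)


def test_summary_matches_brute_force_recount():
    """fixation/tunneling estimates agree with a direct recount of raw
    per-replicate outcome flags (oracle equivalence)."""
    cfg = SimConfig(
        N=30,
        tau=5,
        effect_dist=EffectDistribution("lognormal", 1e-3),
        valley=ValleyParams(r1=0.95, r2=20.0, u1=2e-3, u2=4e-3),
        t_max=30 * 2000,
        seed=17,
    )
    results = run_ensemble(cfg, 200, master_seed=17)
    summ = summarize(results)
    # brute force from raw step records
    n_fix = sum(1 for r in results if r.s2_fix_step is not None)
    n_joint = sum(
        1
        for r in results
        if r.s2_fix_step is not None
        and (r.s1_fix_step is None or r.s1_fix_step > r.s2_fix_step)
    )
    assert n_fix > 0  # the scenario is chosen so fixation happens
    assert fixation_probability(summ).estimate == n_fix / len(results)
    assert tunneling_probability(summ).estimate == n_joint / n_fix
    assert summ.n_tunneled_and_fixed <= summ.n_s2_fixed <= summ.n_reps


class TestConditionalFixationCurve:
    def _records(self, fitness, success):
        return [
            MutantRecord(i, 1, float(f), bool(s))
            for i, (f, s) in enumerate(zip(fitness, success))
        ]

    def test_all_successful_curve_is_one(self, rng):
        f = rng.normal(1.0, 0.05, 400)
        curve = conditional_fixation_by_fitness(self._records(f, np.ones(400)))
        assert np.nanmax(np.abs(curve.p_fix - 1.0)) < 1e-9
        assert curve.p_fix_overall == 1.0

    def test_coin_flip_success_gives_flat_half(self, rng):
        f = rng.normal(1.0, 0.05, 20000)
        s = rng.random(20000) < 0.5
        curve = conditional_fixation_by_fitness(self._records(f, s))
        central = curve.supported & (np.abs(curve.grid - 1.0) < 0.075)
        assert np.nanmean(np.abs(curve.p_fix[central] - 0.5)) < 0.05

    def test_no_success_signalled(self, rng):
        f = rng.normal(1.0, 0.05, 50)
        with pytest.raises(EstimationError):
            conditional_fixation_by_fitness(self._records(f, np.zeros(50)))
        with pytest.raises(EstimationError):
            conditional_fixation_by_fitness([])

    def test_curve_clipped_and_guarded(self, rng):
        f = rng.normal(1.0, 0.05, 2000)
        s = rng.random(2000) < 0.3
        curve = conditional_fixation_by_fitness(self._records(f, s))
        ok = curve.supported
        assert np.all((curve.p_fix[ok] >= 0) & (curve.p_fix[ok] <= 1))
        assert np.all(np.isnan(curve.p_fix[~ok]))


class TestSteadyStateSample:
    def test_zero_variance_all_ones(self):
        cfg = SimConfig(N=20, effect_dist=EffectDistribution("lognormal", 0.0),
                        valley=ValleyParams(u1=0.0, u2=0.0),
                        t_max=20 * 60, snapshot_generations=(50,), seed=1)
        res = run_ensemble(cfg, 5, master_seed=1)
        values, mean, var = steady_state_sample(res, 50)
        assert np.all(values == 1.0) and mean == 1.0 and var == 0.0

    def test_missing_snapshot_errors(self):
        cfg = SimConfig(N=20, t_max=20 * 10, seed=1)
        res = run_ensemble(cfg, 2, master_seed=1)
        with pytest.raises(EstimationError):
            steady_state_sample(res, 5)

    @staticmethod
    def _ss_variance_ci(tau, V, n_reps=1000):
        """Bootstrap 95% CI of the pooled steady-state variance."""
        gen = max(10 * tau, 100) + 20
        cfg = SimConfig(
            N=100, tau=tau, effect_dist=EffectDistribution("lognormal", V),
            valley=ValleyParams(u1=0.0, u2=0.0),
            t_max=100 * (gen + 5), snapshot_generations=(gen,), seed=tau,
        )
        res = run_ensemble(cfg, n_reps, master_seed=tau)
        per_rep = [
            np.var(r.snapshots[gen][0] / r.snapshots[gen][0].mean()) for r in res
        ]
        rng = np.random.default_rng(0)
        boot = [np.mean(rng.choice(per_rep, len(per_rep))) for _ in range(300)]
        return np.percentile(boot, [2.5, 97.5])

    def test_variance_increases_with_tau(self):
        """Pooled steady-state variance at tau=50 exceeds tau=1 at equal V,
        with non-overlapping bootstrap CIs over 1000-replicate estimates
        (persistence widens the steady-state fitness distribution)."""
        lo_tau = self._ss_variance_ci(1, 1e-4)
        hi_tau = self._ss_variance_ci(50, 1e-4)
        assert hi_tau[0] > lo_tau[1]

    def test_variance_increases_with_effect_variance(self):
        """Pooled steady-state variance grows with the per-division V at
        fixed tau (extremes V=1e-5 vs 1e-3, non-overlapping CIs)."""
        lo_v = self._ss_variance_ci(10, 1e-5)
        hi_v = self._ss_variance_ci(10, 1e-3)
        assert hi_v[0] > lo_v[1]


class TestCalibration:
    def test_target_zero_returns_zero(self):
        assert calibrate_effect_variance(0.0, tau=10) == 0.0

    def test_tau1_identity(self):
        """At tau=1 the steady state IS the effect distribution, so the
        calibrated V equals the target variance (within tolerance)."""
        target = 1e-4
        v = calibrate_effect_variance(
            target, tau=1, n_reps=150, seed=5, rel_tol=0.10
        )
        assert 0.7 * target < v < 1.3 * target

    def test_tau10_needs_smaller_V(self):
        v = calibrate_effect_variance(1e-4, tau=10, n_reps=100, seed=5)
        assert v < 1e-4

    def test_non_bracketing_signalled(self):
        with pytest.raises(EstimationError):
            calibrate_effect_variance(10.0, tau=1, v_max=1e-3, n_reps=20, seed=1)
        with pytest.raises(ValueError):
            calibrate_effect_variance(-1.0, tau=1)
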