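"""Summary estimators over simulation ensembles.

Fixation probability is the proportion of replicates in which the final stage
fixes before the truncation time.  The tunneling probability is conditional:
P(tunnel | fix) = P(tunnel and fix) / P(fix), where a replicate "tunneled" if
the final stage fixed without the intermediate stage ever reaching 100%
frequency first.  Confidence intervals are 95% Wilson score intervals.

``conditional_fixation_by_fitness`` applies Bayes' rule to de-novo mutant
birth records:  P(fix | fitness) = P(fitness | fix) P(fix) / P(fitness), with
the two densities estimated by Gaussian kernel smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde
from statsmodels.stats.proportion import proportion_confint

from .effects import EffectDistribution
from .engine import MutantRecord, SimConfig, SimulationResult, run_ensemble

__all__ = [
    "EnsembleSummary",
    "ConditionalFixCurve",
    "EstimationError",
    "summarize",
    "fixation_probability",
    "tunneling_probability",
    "conditional_fixation_by_fitness",
    "proportion_se_bound",
    "steady_state_sample",
    "calibrate_effect_variance",
]


class EstimationError(RuntimeError):
    """Raised when an estimator is undefined for the given ensemble."""


@dataclass(frozen=True)
class EnsembleSummary:
    n_reps: int
    n_s2_fixed: int
    n_tunneled_and_fixed: int
    n_s1_ever_fixed_and_s2_fixed: int
    s2_fixed_flags: tuple
    tunneled_flags: tuple

    def __post_init__(self):
        if not (
            0 <= self.n_tunneled_and_fixed <= self.n_s2_fixed <= self.n_reps
        ):
            raise ValueError("inconsistent ensemble counts")


@dataclass(frozen=True)
class ProportionEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class ConditionalFixCurve:
    """Smoothed P(fix final stage | relative fitness at birth)."""

    grid: np.ndarray
    p_fix: np.ndarray  # clipped to [0, 1]; NaN outside the supported region
    density_all: np.ndarray
    density_success: np.ndarray
    p_fix_overall: float
    supported: np.ndarray  # bool mask: denominator density above threshold

    def to_frame(self):
        """Curve table (columns fitness_grid, p_fix) for CSV export."""
        import pandas as pd

        return pd.DataFrame({"fitness_grid": self.grid, "p_fix": self.p_fix})


def summarize(results: Sequence[SimulationResult]) -> EnsembleSummary:
    s2 = tuple(bool(r.s2_fixed) for r in results)
    tun = tuple(bool(r.tunneled) for r in results)
    n_fix = sum(s2)
    n_joint = sum(t and f for t, f in zip(tun, s2))
    return EnsembleSummary(
        n_reps=len(results),
        n_s2_fixed=n_fix,
        n_tunneled_and_fixed=n_joint,
        n_s1_ever_fixed_and_s2_fixed=n_fix - n_joint,
        s2_fixed_flags=s2,
        tunneled_flags=tun,
    )


def _wilson(k: int, n: int) -> ProportionEstimate:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return ProportionEstimate(k / n, float(lo), float(hi), n)


def fixation_probability(summary: EnsembleSummary) -> ProportionEstimate:
    """Proportion of replicates with final-stage fixation, with 95% CI."""
    if summary.n_reps < 1:
        raise EstimationError("empty ensemble")
    return _wilson(summary.n_s2_fixed, summary.n_reps)


def tunneling_probability(summary: EnsembleSummary) -> ProportionEstimate:
    """P(tunnel | fix): joint tunneling-and-fixation count over fixation count."""
    if summary.n_s2_fixed < 1:
        raise EstimationError(
            "tunneling probability is undefined: no replicate fixed the final stage"
        )
    return _wilson(summary.n_tunneled_and_fixed, summary.n_s2_fixed)


def proportion_se_bound(n_events: int) -> float:
    """Largest possible standard error of a proportion estimated from n events.

    max over p of sqrt(p(1-p)/n) = 0.5/sqrt(n); e.g. 0.0158 for n = 1000.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    return 0.5 / math.sqrt(n_events)


def conditional_fixation_by_fitness(
    mutant_births: Sequence[MutantRecord],
    bandwidth: str | float = "silverman",
    grid: np.ndarray | None = None,
    n_grid: int = 256,
    support_threshold: float = 0.01,
) -> ConditionalFixCurve:
    """Bayes-rule estimate of P(fix final stage | relative fitness at birth).

    Both densities use Gaussian KDEs (``bandwidth`` as accepted by
    ``scipy.stats.gaussian_kde``).  The curve is clipped to [0, 1] and only
    reported where the marginal fitness density exceeds
    ``support_threshold`` times its maximum, guarding the ratio against
    blow-up in the tails.
    """
    fit = np.array([r.relative_fitness_at_birth for r in mutant_births], float)
    succ = np.array([r.founded_fixing_lineage for r in mutant_births], bool)
    if fit.size == 0:
        raise EstimationError("no mutant birth records")
    if not succ.any():
        raise EstimationError("no successful mutant lineages in the ensemble")
    p_overall = succ.mean()
    kde_all = gaussian_kde(fit, bw_method=bandwidth)
    kde_succ = gaussian_kde(fit[succ], bw_method=bandwidth)
    if grid is None:
        lo, hi = fit.min(), fit.max()
        pad = 0.05 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, n_grid)
    grid = np.asarray(grid, float)
    dens_all = kde_all(grid)
    dens_succ = kde_succ(grid)
    supported = dens_all > support_threshold * dens_all.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = np.clip(dens_succ * p_overall / dens_all, 0.0, 1.0)
    curve[~supported] = np.nan
    return ConditionalFixCurve(
        grid=grid,
        p_fix=curve,
        density_all=dens_all,
        density_success=dens_succ,
        p_fix_overall=float(p_overall),
        supported=supported,
    )


def steady_state_sample(
    results: Sequence[SimulationResult],
    at_generation: float,
    normalize: str = "replicate_mean",
):
    """Pooled relative-fitness sample at a snapshot generation.

    With ``normalize="replicate_mean"`` (default) each individual's absolute
    fitness is divided by its own replicate's mean, making replicates whose
    absolute mean has drifted comparable.  ``normalize="none"`` pools the raw
    fitness values (already relative to the stage multiplier when r0=1);
    this preserves atomic distributions such as the centered Bernoulli
    exactly.  Returns ``(values, mean, variance)``.
    """
    if normalize not in ("replicate_mean", "none"):
        raise ValueError(f"unknown normalize option {normalize!r}")
    pooled = []
    for r in results:
        if at_generation not in r.snapshots:
            raise EstimationError(
                f"no snapshot at generation {at_generation}; configure "
                f"snapshot_generations before running"
            )
        w, _stage = r.snapshots[at_generation]
        pooled.append(w / w.mean() if normalize == "replicate_mean" else w)
    values = np.concatenate(pooled)
    return values, float(values.mean()), float(values.var())


def _measure_ss_variance(
    V: float,
    tau: float,
    base_cfg: SimConfig,
    n_reps: int,
    measure_generation: float,
    seed: int,
) -> float:
    from dataclasses import replace
    from .engine import ValleyParams

    dist = EffectDistribution(base_cfg.effect_dist.family, V)
    valley = ValleyParams(
        r0=base_cfg.valley.r0, r1=base_cfg.valley.r1, r2=base_cfg.valley.r2,
        u1=0.0, u2=0.0,
    )
    cfg = replace(
        base_cfg,
        effect_dist=dist,
        tau=tau,
        valley=valley,
        t_max=int(round(measure_generation * base_cfg.N)) + base_cfg.N,
        snapshot_generations=(measure_generation,),
        trace_stride=0,
        init_s1=0,
    )
    results = run_ensemble(cfg, n_reps, master_seed=seed)
    _values, _mean, var = steady_state_sample(results, measure_generation)
    return var


def calibrate_effect_variance(
    target_ss_variance: float,
    tau: float,
    base_cfg: SimConfig | None = None,
    *,
    v_max: float = 0.1,
    rel_tol: float = 0.10,
    n_reps: int = 200,
    seed: int = 0,
    max_iter: int = 40,
) -> float:
    """Find the per-division effect variance V whose steady-state pooled
    fitness variance matches a target, by monotone bisection.

    The steady-state variance grows with both V and tau, so matching a target
    across tau values requires smaller V at larger tau.  Each candidate V is
    evaluated with the same fixed replicate budget and seed schedule, making
    the bracketing function deterministic and (statistically) monotone.
    Burn-in before measurement is max(10*tau, 100) + 20 generations.
    """
    if target_ss_variance < 0:
        raise ValueError("target variance must be >= 0")
    if target_ss_variance == 0.0:
        return 0.0
    base_cfg = SimConfig() if base_cfg is None else base_cfg
    measure_gen = (100.0 if math.isinf(tau) else max(10 * tau, 100)) + 20
    if math.isinf(tau):
        raise ValueError("steady-state calibration requires finite tau")

    def f(V):
        return _measure_ss_variance(V, tau, base_cfg, n_reps, measure_gen, seed)

    lo, hi = 0.0, float(v_max)
    f_hi = f(hi)
    if f_hi < target_ss_variance:
        raise EstimationError(
            f"target variance {target_ss_variance} not bracketed by V in "
            f"[0, {v_max}] (achieved {f_hi} at V={v_max})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target_ss_variance) <= rel_tol * target_ss_variance:
            return mid
        if val < target_ss_variance:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
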