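"""Modified Moran process over a two-step fitness valley.

The population holds exactly ``N`` asexual individuals in three evolutionary
stages: initial S0 (stage fitness ``r0 = 1``), deleterious intermediate S1
(``r1 < r0``) and advantageous final S2 (``r2 > r0``).  Each elementary step,
one individual reproduces with probability proportional to its absolute
fitness and another, chosen uniformly among the rest, dies.  The mother's two
daughters share one freshly drawn stochastic fitness effect on top of the
mother's inherited effect buffer; the daughter replacing the dead individual
may advance one stage with probability ``u1`` (S0) or ``u2`` (S1).  There is
no back mutation.  A "generation" is ``N`` elementary steps.

Absolute fitness is ``w = r_j * prod(m_k)`` over the active effects
(multiplicative scale) or ``w = max(eps, r_j + sum(m_k - 1))`` (additive
scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .effects import (
    EPS,
    ConfigurationError,
    EffectBuffer,
    EffectDistribution,
    apply_lifetime_step,
    draw_effect,
)

__all__ = [
    "ValleyParams",
    "SimConfig",
    "Individual",
    "MutantRecord",
    "SimulationResult",
    "elementary_step",
    "run_simulation",
    "run_ensemble",
    "additive_fitness",
    "child_seeds",
]


@dataclass(frozen=True)
class ValleyParams:
    """Stage fitness multipliers and forward mutation probabilities.

    ``r2 > r0 > r1 > 0`` defines the valley: the intermediate stage is
    deleterious, the final stage advantageous.  ``u1`` (``u2``) is the
    probability per reproduction that an S0 (S1) mother's replacing daughter
    advances one stage.

    ``enforce_valley=False`` relaxes the ordering constraint (multipliers
    must still be positive).  This is for non-valley scenarios such as the
    classical single-type Moran fixation benchmark, where the "intermediate"
    stage may be neutral or advantageous; the configuration-file interface
    always validates the ordering.
    """

    r0: float = 1.0
    r1: float = 0.95
    r2: float = 5.0
    u1: float = 1e-4
    u2: float = 2e-4
    enforce_valley: bool = True

    def __post_init__(self):
        if not self.enforce_valley:
            if min(self.r0, self.r1, self.r2) <= 0.0:
                raise ConfigurationError("stage fitness multipliers must be > 0")
        elif not (self.r2 > self.r0 > self.r1 > 0.0):
            raise ConfigurationError(
                f"valley requires r2 > r0 > r1 > 0, got "
                f"r0={self.r0}, r1={self.r1}, r2={self.r2}"
            )
        for name in ("u1", "u2"):
            u = getattr(self, name)
            if not (0.0 <= u <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {u}")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run.

    ``tau`` may be a positive integer or ``math.inf`` (permanent effects).
    ``t_max`` is in elementary steps and defaults to ``3650 * N`` (3650
    generations).  ``snapshot_generations`` lists generations at which the
    full population fitness vector is stored; ``trace_stride`` (elementary
    steps) enables a mean/variance fitness trace, 0 disables it.
    ``init_s1`` seeds the initial population with that many S1 individuals
    (the rest are S0, all with empty effect buffers).
    """

    N: int = 100
    effect_dist: EffectDistribution = field(
        default_factory=lambda: EffectDistribution("lognormal", 1e-4)
    )
    tau: float = 100
    lifetime_mode: str = "deterministic"
    scale_mode: str = "multiplicative"
    valley: ValleyParams = field(default_factory=ValleyParams)
    t_max: int | None = None
    seed: int = 0
    trace_stride: int = 0
    snapshot_generations: tuple = ()
    init_s1: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ConfigurationError(f"population size N must be >= 2, got {self.N}")
        if not (self.tau >= 1):
            raise ConfigurationError(f"tau must be >= 1 (or inf), got {self.tau}")
        if self.lifetime_mode not in ("deterministic", "geometric"):
            raise ConfigurationError(f"unknown lifetime_mode {self.lifetime_mode!r}")
        if self.scale_mode not in ("multiplicative", "additive"):
            raise ConfigurationError(f"unknown scale_mode {self.scale_mode!r}")
        if self.t_max is not None and self.t_max < 1:
            raise ConfigurationError("t_max must be >= 1")
        if not (0 <= self.init_s1 <= self.N):
            raise ConfigurationError("init_s1 must be in [0, N]")

    @property
    def steps(self) -> int:
        return int(self.t_max) if self.t_max is not None else 3650 * self.N

    def generations_to_steps(self, g: float) -> int:
        return int(round(g * self.N))


@dataclass
class Individual:
    """One cell: evolutionary stage (0/1/2), active-effect buffer, divisions."""

    stage: int = 0
    buffer: EffectBuffer = field(default_factory=EffectBuffer)
    division_count: int = 0

    def fitness(self, valley: ValleyParams, scale_mode: str = "multiplicative") -> float:
        r = (valley.r0, valley.r1, valley.r2)[self.stage]
        if scale_mode == "additive":
            return additive_fitness(r, self.buffer)
        return r * self.buffer.background()


def additive_fitness(r_j: float, buffer: EffectBuffer) -> float:
    """Additive-scale fitness ``max(eps, r_j + sum(m_k - 1))``."""
    return max(EPS, r_j + buffer.additive_offset())


@dataclass(frozen=True)
class MutantRecord:
    """A de-novo stage-advance birth."""

    birth_step: int
    stage_created: int  # 1 or 2
    relative_fitness_at_birth: float  # mutant w / population mean w at that step
    founded_fixing_lineage: bool


@dataclass
class SimulationResult:
    """Outcome of one replicate."""

    s1_fixed: bool
    s1_fix_step: int | None
    s2_fixed: bool
    s2_fix_step: int | None
    tunneled: bool  # S2 fixed without S1 ever reaching 100% first
    n_steps: int
    n_s1_births: int
    n_s2_births: int
    mutant_births: list[MutantRecord]
    seed: int
    trace: pd.DataFrame | None = None
    snapshots: dict = field(default_factory=dict)  # generation -> (w, stage) arrays

    def mutant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "birth_step": [r.birth_step for r in self.mutant_births],
                "stage": [r.stage_created for r in self.mutant_births],
                "relative_fitness": [
                    r.relative_fitness_at_birth for r in self.mutant_births
                ],
                "founded_fixing_lineage": [
                    r.founded_fixing_lineage for r in self.mutant_births
                ],
            }
        )


# ---------------------------------------------------------------------------
# pure-Python single step (reference semantics; the ensemble path is compiled)


def elementary_step(
    population: list[Individual],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    forced_effect: float | None = None,
) -> dict:
    """Advance a population (modified in place) by one birth-death event.

    Returns an event dict with the reproducer index, death index, the shared
    effect draw and the stage mutation (if any).  ``forced_effect`` overrides
    the random effect draw, for hand-computed checks.
    """
    N = len(population)
    w = np.array([ind.fitness(cfg.valley, cfg.scale_mode) for ind in population])
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise RuntimeError("non-finite or non-positive fitness encountered")
    mom_idx = int(rng.choice(N, p=w / w.sum()))
    d_idx = int(rng.integers(N - 1))
    if d_idx >= mom_idx:
        d_idx += 1

    mom = population[mom_idx]
    dist = cfg.effect_dist
    if cfg.lifetime_mode == "geometric" and not math.isinf(cfg.tau):
        n_new = rng.poisson(1.0)
        new = dist.rvs(n_new, rng=rng) if forced_effect is None else [forced_effect]
        apply_lifetime_step(mom.buffer, new, "geometric", cfg.tau, rng)
        drawn = list(np.atleast_1d(new))
    else:
        m = draw_effect(dist, rng) if forced_effect is None else float(forced_effect)
        apply_lifetime_step(mom.buffer, m, "deterministic", cfg.tau, rng)
        drawn = [m]
    mom.division_count += 1

    # replacing daughter: identical copy of the mother's post-division state
    daughter = Individual(mom.stage, mom.buffer.copy(), mom.division_count)
    mutation = None
    if daughter.stage == 0 and rng.random() < cfg.valley.u1:
        daughter.stage = 1
        mutation = 1
    elif daughter.stage == 1 and rng.random() < cfg.valley.u2:
        daughter.stage = 2
        mutation = 2
    population[d_idx] = daughter
    return {
        "reproducer": mom_idx,
        "death": d_idx,
        "effects": drawn,
        "mutation": mutation,
    }


# ---------------------------------------------------------------------------
# compiled ensemble path


def _mode_code(cfg: SimConfig) -> int:
    if math.isinf(cfg.tau):
        return _kernels.MODE_INF
    return _kernels.MODE_GEOM if cfg.lifetime_mode == "geometric" else _kernels.MODE_DET


def _family_params(dist: EffectDistribution) -> tuple[float, float]:
    V = dist.V
    if V == 0.0:
        return 0.0, 0.0
    if dist.family == "lognormal":
        s2 = math.log1p(V)
        return -0.5 * s2, math.sqrt(s2)
    if dist.family == "gamma":
        return 1.0 / V, V
    if dist.family == "laplace":
        return 1.0, math.sqrt(V / 2.0)
    lo, hi = dist.support_points
    return lo, hi


def _buffer_capacity(cfg: SimConfig) -> int:
    if math.isinf(cfg.tau) or cfg.effect_dist.V == 0.0:
        return 1
    tau = int(cfg.tau)
    if cfg.lifetime_mode == "geometric":
        # stationary active-event count is ~Poisson(tau); leave wide headroom
        return tau + int(10 * math.sqrt(tau)) + 20
    return tau


def run_simulation(cfg: SimConfig, seed: int | None = None) -> SimulationResult:
    """Run one replicate until final-stage fixation or ``t_max`` steps."""
    seed = cfg.seed if seed is None else int(seed)
    t_max = cfg.steps
    snap_steps = np.array(
        sorted(cfg.generations_to_steps(g) for g in cfg.snapshot_generations),
        dtype=np.int64,
    )
    u = cfg.valley
    rec_cap = max(1024, int(10 * (u.u1 + u.u2) * t_max) + 64)
    dist = cfg.effect_dist
    p1, p2 = _family_params(dist)
    out = _kernels.run_core(
        cfg.N,
        t_max,
        np.uint32(seed % (2**31)),
        dist.family_code,
        dist.V,
        1 if math.isinf(cfg.tau) else int(cfg.tau),
        _mode_code(cfg),
        cfg.scale_mode == "multiplicative",
        p1,
        p2,
        u.r0,
        u.r1,
        u.r2,
        u.u1,
        u.u2,
        cfg.init_s1,
        snap_steps,
        int(cfg.trace_stride),
        rec_cap,
        _buffer_capacity(cfg),
    )
    (
        s1_fix,
        s2_fix,
        n_steps,
        n_s1_births,
        n_s2_births,
        nrec,
        rec_step,
        rec_stage,
        rec_relfit,
        rec_success,
        ntr,
        tr_step,
        tr_cnt,
        tr_meanw,
        tr_varw,
        isnap,
        snap_w,
        snap_stage,
    ) = out

    records = [
        MutantRecord(int(rec_step[i]), int(rec_stage[i]), float(rec_relfit[i]),
                     bool(rec_success[i]))
        for i in range(nrec)
    ]
    trace = None
    if ntr > 0:
        trace = pd.DataFrame(
            {
                "step": tr_step,
                "n_s0": tr_cnt[:, 0],
                "n_s1": tr_cnt[:, 1],
                "n_s2": tr_cnt[:, 2],
                "mean_w": tr_meanw,
                "var_w": tr_varw,
            }
        )
        trace["generation"] = trace["step"] / cfg.N
    snapshots = {}
    gens = sorted(cfg.snapshot_generations)
    for k in range(int(isnap)):
        snapshots[gens[k]] = (snap_w[k].copy(), snap_stage[k].copy())

    return SimulationResult(
        s1_fixed=s1_fix >= 0,
        s1_fix_step=int(s1_fix) if s1_fix >= 0 else None,
        s2_fixed=s2_fix >= 0,
        s2_fix_step=int(s2_fix) if s2_fix >= 0 else None,
        tunneled=(s2_fix >= 0) and (s1_fix < 0),
        n_steps=int(n_steps),
        n_s1_births=int(n_s1_births),
        n_s2_births=int(n_s2_births),
        mutant_births=records,
        seed=seed,
        trace=trace,
        snapshots=snapshots,
    )


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def run_ensemble(
    cfg: SimConfig, n_reps: int, master_seed: int | None = None
) -> list[SimulationResult]:
    """Run ``n_reps`` independent replicates with derived child seeds."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    master = cfg.seed if master_seed is None else int(master_seed)
    seeds = child_seeds(master, n_reps)
    return [run_simulation(cfg, seed=int(s)) for s in seeds]


def results_table(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Per-replicate summary rows (the CSV emitted by the CLI)."""
    return pd.DataFrame(
        {
            "replicate": np.arange(len(results)),
            "seed": [r.seed for r in results],
            "s1_fix_step": [r.s1_fix_step if r.s1_fixed else -1 for r in results],
            "s2_fix_step": [r.s2_fix_step if r.s2_fixed else -1 for r in results],
            "tunneled": [r.tunneled for r in results],
            "n_mutant_births": [r.n_s1_births + r.n_s2_births for r in results],
            "n_s1_births": [r.n_s1_births for r in results],
        }
    )
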