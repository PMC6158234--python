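"""Distributions and lifetimes of stochastic, heritable fitness effects.

Every reproductive event draws a multiplicative fitness effect ``m`` from a
distribution ``F`` with mean 1 (neutral on average) and variance ``V``.  An
effect stays active in a lineage for a finite number of divisions — its
*lifetime* — after which it is forgotten.  Two lifetime models are supported:

* ``deterministic`` — every effect persists through exactly ``tau`` divisions,
  counting the division at which it was acquired.  A cell therefore carries a
  FIFO buffer of at most ``tau`` active effects.
* ``geometric`` — each reproduction creates a Poisson(1) number of separate
  effect events; at every subsequent division each active event reverts
  independently with probability ``1/tau``, so lifetimes are geometric with
  mean ``tau``.

``tau = inf`` makes effects permanent; the buffer is then collapsed into a
single running accumulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EFFECT_FAMILIES",
    "EPS",
    "EffectDistribution",
    "EffectBuffer",
    "make_effect_distribution",
    "draw_effect",
    "apply_lifetime_step",
]

#: Positivity guard: drawn effects below this are clamped (fitness must stay > 0).
EPS = 1e-9

EFFECT_FAMILIES = ("lognormal", "gamma", "laplace", "bernoulli")

_ALIASES = {
    "log-normal": "lognormal",
    "lognormal": "lognormal",
    "gamma": "gamma",
    "laplace": "laplace",
    "double-exponential": "laplace",
    "exponential": "laplace",
    "bernoulli": "bernoulli",
    "centered-bernoulli": "bernoulli",
    "centered bernoulli": "bernoulli",
}

# integer codes shared with the numba kernel
FAMILY_CODES = {"lognormal": 0, "gamma": 1, "laplace": 2, "bernoulli": 3}


class ConfigurationError(ValueError):
    """Raised for invalid distribution/simulation configuration."""


@dataclass(frozen=True)
class EffectDistribution:
    """A mean-1, variance-``V`` distribution of multiplicative fitness effects.

    Parameters are derived from the moment constraints:

    * ``lognormal``:  ``sigma^2 = ln(1+V)``, ``mu = -sigma^2/2``
    * ``gamma``:      shape ``1/V``, scale ``V``
    * ``laplace``:    location 1, scale ``sqrt(V/2)``
    * ``bernoulli``:  equal mass on ``1 - sqrt(V)`` and ``1 + sqrt(V)``

    ``V = 0`` degenerates to a point mass at exactly 1 for every family.
    """

    family: str
    V: float

    def __post_init__(self):
        fam = _ALIASES.get(str(self.family).lower())
        if fam is None:
            raise ConfigurationError(
                f"unknown effect distribution family {self.family!r}; "
                f"choose one of {EFFECT_FAMILIES}"
            )
        if not (self.V >= 0.0):
            raise ConfigurationError(f"effect variance V must be >= 0, got {self.V}")
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "V", float(self.V))

    @property
    def family_code(self) -> int:
        return FAMILY_CODES[self.family]

    @property
    def mean(self) -> float:
        return 1.0

    @property
    def variance(self) -> float:
        return self.V

    def _frozen(self):
        """The underlying scipy frozen distribution (V > 0 only)."""
        V = self.V
        if self.family == "lognormal":
            s2 = math.log1p(V)
            return stats.lognorm(s=math.sqrt(s2), scale=math.exp(-0.5 * s2))
        if self.family == "gamma":
            return stats.gamma(a=1.0 / V, scale=V)
        if self.family == "laplace":
            return stats.laplace(loc=1.0, scale=math.sqrt(V / 2.0))
        # bernoulli: two-point distribution
        return stats.rv_discrete(
            values=([0, 1], [0.5, 0.5])  # indices into support; see .rvs below
        )

    @property
    def support_points(self) -> tuple[float, float] | None:
        """Two-point support for the centered Bernoulli family, else ``None``."""
        if self.family != "bernoulli":
            return None
        r = math.sqrt(self.V)
        return (1.0 - r, 1.0 + r)

    def rvs(self, size=None, rng: np.random.Generator | None = None):
        """Draw effects; strictly positive after the positivity guard."""
        rng = np.random.default_rng() if rng is None else rng
        if self.V == 0.0:
            return 1.0 if size is None else np.ones(size)
        if self.family == "lognormal":
            s2 = math.log1p(self.V)
            out = rng.lognormal(-0.5 * s2, math.sqrt(s2), size)
        elif self.family == "gamma":
            out = rng.gamma(1.0 / self.V, self.V, size)
        elif self.family == "laplace":
            out = rng.laplace(1.0, math.sqrt(self.V / 2.0), size)
        else:
            lo, hi = self.support_points
            out = np.where(rng.random(size) < 0.5, lo, hi)
        return np.maximum(out, EPS)

    def cdf(self, x):
        """CDF of the (un-guarded) effect distribution; V > 0 required."""
        if self.V == 0.0:
            return np.where(np.asarray(x, float) >= 1.0, 1.0, 0.0)
        if self.family == "bernoulli":
            lo, hi = self.support_points
            x = np.asarray(x, float)
            return np.where(x >= hi, 1.0, np.where(x >= lo, 0.5, 0.0))
        return self._frozen().cdf(x)


def make_effect_distribution(family: str, V: float) -> EffectDistribution:
    """Construct a mean-1, variance-``V`` effect distribution."""
    return EffectDistribution(family, V)


def draw_effect(dist: EffectDistribution, rng: np.random.Generator) -> float:
    """Draw a single effect ``m_k > 0`` from ``dist``."""
    return float(dist.rvs(rng=rng))


@dataclass
class EffectBuffer:
    """The set of fitness effects currently active in one cell's lineage.

    ``background()`` is the product of all active effects (1 for an empty
    buffer).  For ``tau = inf`` the buffer stores a single accumulated
    log-background instead of an unbounded list.
    """

    tau: float = 1  # int >= 1, or math.inf
    mode: str = "deterministic"  # or "geometric"
    effects: list = field(default_factory=list)
    _log_acc: float = 0.0  # tau=inf: sum of log(m)
    _add_acc: float = 0.0  # tau=inf: sum of (m - 1), for the additive scale

    def __post_init__(self):
        if self.mode not in ("deterministic", "geometric"):
            raise ConfigurationError(f"unknown lifetime mode {self.mode!r}")
        if not (self.tau >= 1):
            raise ValueError(f"effect lifetime tau must be >= 1, got {self.tau}")

    @property
    def infinite(self) -> bool:
        return math.isinf(self.tau)

    def background(self) -> float:
        if self.infinite:
            return math.exp(self._log_acc)
        prod = 1.0
        for m in self.effects:
            prod *= m
        return prod

    def log_background(self) -> float:
        if self.infinite:
            return self._log_acc
        return sum(math.log(m) for m in self.effects)

    def additive_offset(self) -> float:
        """Sum of (m - 1) over active effects, for the additive fitness scale."""
        if self.infinite:
            return self._add_acc
        return sum(m - 1.0 for m in self.effects)

    def copy(self) -> "EffectBuffer":
        return EffectBuffer(
            self.tau, self.mode, list(self.effects), self._log_acc, self._add_acc
        )


def apply_lifetime_step(
    buffer: EffectBuffer,
    new_effects,
    mode: str | None = None,
    tau: float | None = None,
    rng: np.random.Generator | None = None,
) -> EffectBuffer:
    """Advance a buffer through one division, adding newly acquired effects.

    ``new_effects`` is a scalar (deterministic / infinite lifetime: the single
    combined effect of this division) or a sequence (geometric mode: the
    Poisson-many separate events of this division).  In geometric mode every
    pre-existing event first reverts independently with probability
    ``1/tau`` — new events are exempt, so the minimum lifetime is one
    division.  In deterministic mode the oldest effect is evicted once the
    buffer would exceed ``tau`` (FIFO).  The buffer is modified in place and
    returned.
    """
    mode = buffer.mode if mode is None else mode
    tau = buffer.tau if tau is None else tau
    if not (tau >= 1):
        raise ValueError(f"effect lifetime tau must be >= 1, got {tau}")
    new = np.atleast_1d(np.asarray(new_effects, dtype=float))
    if np.any(new <= 0):
        raise ValueError("fitness effects must be strictly positive")

    if math.isinf(tau):
        for m in new:
            buffer._log_acc += math.log(m)
            buffer._add_acc += m - 1.0
        return buffer

    if mode == "deterministic":
        for m in new:
            buffer.effects.append(float(m))
            if len(buffer.effects) > tau:
                buffer.effects.pop(0)
        return buffer

    if mode == "geometric":
        if rng is None:
            raise ValueError("geometric lifetime mode requires an rng")
        keep = rng.random(len(buffer.effects)) >= 1.0 / tau
        buffer.effects = [m for m, k in zip(buffer.effects, keep) if k]
        buffer.effects.extend(float(m) for m in new)
        return buffer

    raise ConfigurationError(f"unknown lifetime mode {mode!r}")
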