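"""Synthetic single-cell lineage trees with variable interdivision times.

Stands in for single-cell time-lapse datasets (full binary lineage trees in
which every cell's interdivision time, IDT, is recorded).  Two marginal IDT
models are available: an exponentially modified Gaussian (EMG), appropriate
for PC9-like cells, or reciprocals of a user-supplied simulated fitness
sample.  Sister cells can be given a tunable IDT correlation through a shared
Gaussian latent factor per division, mapped onto the marginal through its
quantile function (a Gaussian copula), which preserves the requested marginal
exactly while making the sister correlation monotone in the latent loading.

Optionally, a heritable multiplicative "speed" factor with finite lifetime
``heritability_tau`` — the same effect-buffer mechanism as the evolutionary
simulation — divides each cell's IDT, inducing correlations that persist
beyond sisters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import EffectBuffer, EffectDistribution, apply_lifetime_step
from .gof import EMGModel, emg_interdivision_model

__all__ = ["generate_lineages", "DEFAULT_EMG"]

#: PC9-like EMG interdivision-time parameters (hours).
DEFAULT_EMG = emg_interdivision_model(mu=15.0, sigma=1.0, lam_mean=3.0)


def _empirical_ppf(base: np.ndarray):
    base = np.sort(np.asarray(base, float))

    def ppf(q):
        return np.quantile(base, np.clip(q, 0.0, 1.0), method="linear")

    return ppf


def generate_lineages(
    n_lineages: int = 30,
    generations: int = 7,
    idt_model="emg",
    sister_correlation: float = 0.0,
    heritability_tau: float | None = None,
    seed: int = 0,
    *,
    emg: EMGModel | None = None,
    fitness_values: np.ndarray | None = None,
    mean_idt: float = 20.0,
    effect_dist: EffectDistribution | None = None,
) -> pd.DataFrame:
    """Generate a table of lineage cells with interdivision times.

    Returns a DataFrame with columns ``lineage_id, cell_id, parent_id,
    generation, idt`` (hours; ``parent_id`` is -1 for founder cells).  Each
    lineage is a complete binary tree of depth ``generations``: the founder is
    generation 0 and each cell of generation g < generations has two
    daughters.

    ``idt_model`` is ``"emg"`` (marginal from ``emg``, default PC9-like) or
    ``"reciprocal_fitness"`` (marginal from ``mean_idt`` times the normalized
    reciprocals of ``fitness_values``).  ``sister_correlation`` in [0, 1]
    sets the latent Gaussian correlation between sister IDTs.
    """
    if not (0.0 <= sister_correlation <= 1.0):
        raise ValueError(
            f"sister_correlation must be in [0, 1], got {sister_correlation}"
        )
    if n_lineages < 1 or generations < 0:
        raise ValueError("need n_lineages >= 1 and generations >= 0")
    rng = np.random.default_rng(seed)

    if idt_model == "emg":
        model = DEFAULT_EMG if emg is None else emg
        ppf = model.ppf
    elif idt_model == "reciprocal_fitness":
        if fitness_values is None:
            raise ValueError("reciprocal_fitness model requires fitness_values")
        f = np.asarray(fitness_values, float)
        if np.any(f <= 0):
            raise ValueError("fitness values must be positive")
        inv = 1.0 / f
        ppf = _empirical_ppf(mean_idt * inv / inv.mean())
    else:
        raise ValueError(f"unknown idt_model {idt_model!r}")

    if heritability_tau is not None:
        if not (heritability_tau >= 1):
            raise ValueError("heritability_tau must be >= 1")
        if effect_dist is None:
            effect_dist = EffectDistribution("lognormal", 1e-2)

    rho = float(sister_correlation)
    a = math.sqrt(rho)
    b = math.sqrt(1.0 - rho)

    rows = []  # (lineage_id, cell_id, parent_id, generation)
    latents = []
    backgrounds = []
    cell_counter = 0
    for lin in range(n_lineages):
        # (cell_id, parent_id, generation, latent, buffer)
        founder_z = rng.standard_normal()
        founder_buf = (
            EffectBuffer(heritability_tau) if heritability_tau is not None else None
        )
        frontier = [(cell_counter, -1, 0, founder_z, founder_buf)]
        cell_counter += 1
        while frontier:
            cid, pid, gen, z, buf = frontier.pop()
            rows.append((lin, cid, pid, gen))
            latents.append(z)
            backgrounds.append(1.0 if buf is None else buf.background())
            if gen < generations:
                shared = rng.standard_normal()
                # sisters share the division's new heritable effect draw
                m = float(effect_dist.rvs(rng=rng)) if buf is not None else None
                for _ in range(2):
                    zc = a * shared + b * rng.standard_normal()
                    if buf is not None:
                        child_buf = buf.copy()
                        apply_lifetime_step(
                            child_buf, m, "deterministic", heritability_tau
                        )
                    else:
                        child_buf = None
                    frontier.append((cell_counter, cid, gen + 1, zc, child_buf))
                    cell_counter += 1
    idt = np.asarray(ppf(norm.cdf(np.array(latents))), float)
    idt = np.maximum(idt / np.array(backgrounds), 1e-6)
    table = pd.DataFrame(
        rows, columns=["lineage_id", "cell_id", "parent_id", "generation"]
    )
    table["idt"] = idt
    return table


def sister_pairs(table: pd.DataFrame) -> np.ndarray:
    """IDT pairs of sister cells, shape (n_pairs, 2)."""
    daughters = table[table["parent_id"] >= 0]
    pairs = []
    for _, grp in daughters.groupby(["lineage_id", "parent_id"]):
        v = grp["idt"].to_numpy()
        if v.size == 2:
            pairs.append(v)
    return np.array(pairs)
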