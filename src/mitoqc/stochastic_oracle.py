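"""Finite-population agent-based simulator used as a correctness oracle.

A population of ``M`` individual mitochondria, each carrying an integer
quality, is evolved with the same processes as the master equation:
fusion-fission reactions executed event-wise with matching propensities,
binomial decay and mitophagy, biogenesis insertions that keep ``M`` fixed
(homeostasis), and agent-level random damage.  The empirical quality
histogram of the population must agree with the master-equation solution
within sampling error; this is the decisive, independent check of the
mean-field bookkeeping (combinatorial weights, rheostat, damage semantics).

Because agents are exchangeable, the population is stored as a per-state
count vector; fusion-fission conserves total quality exactly in integer
arithmetic in conserving mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrator import SimulationConfig
from .operators import effective_infectious_rate, enumerate_events
from .quality_state import QualityDistribution
from .rate_model import selectivity_values

__all__ = [
    "AgentPopulation",
    "OracleSeries",
    "ComparisonResult",
    "simulate_agents",
    "compare_to_master",
]


@dataclass
class AgentPopulation:
    """Counts of mitochondria per quality state at one instant."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative agent counts")

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    @property
    def n_states(self) -> int:
        return self.counts.size

    def qualities(self) -> np.ndarray:
        """Explicit integer quality per agent (for inspection)."""
        return np.repeat(np.arange(self.n_states), self.counts)

    def empirical_distribution(self) -> QualityDistribution:
        return QualityDistribution(self.counts / self.size, self.time)


@dataclass
class OracleSeries:
    """Empirical distributions at the recorded output times."""

    times: np.ndarray
    distributions: np.ndarray  # shape (n_times, n_states)
    population_size: int
    final: AgentPopulation


@dataclass
class ComparisonResult:
    """Per-state agreement of oracle and master-equation distributions."""

    max_abs_discrepancy: float
    z_scores: np.ndarray
    flagged: np.ndarray  # states with |z| > 3

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged.any())


def _initial_counts(
    config: SimulationConfig, population_size: int, rng: np.random.Generator
) -> np.ndarray:
    probs = config.initial_distribution().probs
    return rng.multinomial(population_size, probs / probs.sum())


def simulate_agents(
    config: SimulationConfig,
    population_size: int,
    seed: int,
    output_every: float | None = None,
) -> OracleSeries:
    """Stochastic fixed-timestep simulation of the agent population.

    Each step executes, in order: fusion-fission reactions (Poisson counts
    per listed event at propensity ``a * s(l) * s(m) * n_l * n_m / M``,
    capped by the available agents; damaged output partitions in infectious
    and coupled modes), quality decay (binomial per state), mitophagy with
    immediate compensating biogenesis (multinomial over renewal weights),
    and random damage events.  Population size is constant throughout.
    """
    if population_size < 100:
        import warnings

        warnings.warn(
            "population below 100 agents: sampling noise will dominate",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = config.n_states
    dt = config.dt
    counts = _initial_counts(config, population_size, rng)
    m_total = population_size
    events = enumerate_events(n)
    specs = config.specs
    s_ff = selectivity_values(specs["fusion_fission"].selectivity, n)
    s_decay = selectivity_values(specs["decay"].selectivity, n)
    s_mito = selectivity_values(specs["mitophagy"].selectivity, n)
    s_ren = selectivity_values(specs["renewal"].selectivity, n)
    w_event = s_ff[events.l_in] * s_ff[events.m_in]
    perturbed_mode = config.damage_mode in ("infectious", "coupled")
    random_mode = config.damage_mode in ("random", "coupled")
    eps_max = None
    if perturbed_mode:
        eps_max = specs["infectious_damage"].extras.get("eps_max")
    rd_spec = specs.get("random_damage")
    n_steps = int(round(config.t_end / dt))
    if output_every is None:
        output_every = config.output_every
    out_stride = max(1, int(round(output_every / dt)))
    times = [0.0]
    dists = [counts / m_total]

    levels = np.arange(n)
    for i in range(n_steps):
        t = i * dt
        # --- fusion-fission, event-wise tau leap ---
        a = specs["fusion_fission"].rate(t)
        if a > 0:
            mu = (a * dt / m_total) * w_event * counts[events.l_in] * counts[
                events.m_in
            ]
            n_reactions = rng.poisson(mu)
            active = np.flatnonzero(n_reactions)
            if perturbed_mode:
                id_rate = effective_infectious_rate(specs, t, config.damage_mode)
                p_damage = id_rate / a if a > 0 else 0.0
            for j in rng.permutation(active):
                k = int(n_reactions[j])
                li, mi = int(events.l_in[j]), int(events.m_in[j])
                for _ in range(k):
                    # honour finite supply: skip if inputs unavailable
                    if li == mi:
                        if counts[li] < 2:
                            continue
                    elif counts[li] < 1 or counts[mi] < 1:
                        continue
                    lo, mo = int(events.l_out[j]), int(events.m_out[j])
                    if perturbed_mode and rng.random() < p_damage:
                        h1 = lo if eps_max is None else min(lo, eps_max)
                        h2 = mo if eps_max is None else min(mo, eps_max)
                        lo -= int(rng.integers(0, h1 + 1))
                        mo -= int(rng.integers(0, h2 + 1))
                    counts[li] -= 1
                    counts[mi] -= 1
                    counts[lo] += 1
                    counts[mo] += 1
        # --- decay: each agent steps down independently ---
        p_down = np.clip(specs["decay"].rate(t) * s_decay * dt, 0.0, 1.0)
        p_down[0] = 0.0
        down = rng.binomial(counts, p_down)
        counts -= down
        counts[:-1] += down[1:]
        # --- mitophagy + immediate biogenesis (homeostasis) ---
        p_remove = np.clip(specs["mitophagy"].rate(t) * s_mito * dt, 0.0, 1.0)
        weight = s_ren * counts  # renewal weights before removal
        removed = rng.binomial(counts, p_remove)
        n_removed = int(removed.sum())
        if n_removed:
            wsum = weight.sum()
            if wsum <= 0:
                raise RuntimeError(
                    "oracle homeostasis failed: no state can receive "
                    "biogenesis insertions"
                )
            counts -= removed
            counts += rng.multinomial(n_removed, weight / wsum)
        # --- random damage at the agent level ---
        if random_mode:
            rd_rate = rd_spec.rate(t)
            r_max = rd_spec.extras.get("r_max", 0.5)
            for _ in range(rng.poisson(rd_rate * dt)):
                l = int(rng.integers(1, n))
                sink = int(rng.integers(0, l))
                fraction = r_max * (1.0 - rng.random())
                moved = rng.binomial(counts[l], fraction)
                counts[l] -= moved
                counts[sink] += moved
        if (i + 1) % out_stride == 0 or i == n_steps - 1:
            times.append((i + 1) * dt)
            dists.append(counts / m_total)

    assert counts.sum() == m_total  # homeostasis: population size invariant
    return OracleSeries(
        times=np.asarray(times),
        distributions=np.asarray(dists),
        population_size=m_total,
        final=AgentPopulation(counts, times[-1]),
    )


def compare_to_master(
    oracle_probs: np.ndarray,
    master_probs: np.ndarray,
    population_size: int,
) -> ComparisonResult:
    """Per-state z-scores of the oracle histogram against the master law.

    Standard errors are binomial under the master-equation probabilities,
    floored at ``1/M`` so that states with vanishing expected mass still
    get a finite scale.
    """
    oracle_probs = np.asarray(oracle_probs, dtype=float)
    master_probs = np.asarray(master_probs, dtype=float)
    if oracle_probs.shape != master_probs.shape:
        raise ValueError("oracle and master distributions have different shapes")
    p = np.clip(master_probs, 0.0, 1.0)
    se = np.sqrt(p * (1.0 - p) / population_size)
    se = np.maximum(se, 1.0 / population_size)
    z = (oracle_probs - master_probs) / se
    return ComparisonResult(
        max_abs_discrepancy=float(np.abs(oracle_probs - master_probs).max()),
        z_scores=z,
        flagged=np.abs(z) > 3.0,
    )
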