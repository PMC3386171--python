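"""Quality state-space, probability distributions over it, and scalar readouts.

The mitochondrial population of a cell is described by a probability
distribution ``p(l, t)`` over a finite ladder of discrete functional-quality
states ``l = 0 ... N-1``.  State ``0`` holds fully dysfunctional,
non-fusogenic ("non-active") mitochondria; state ``N-1`` is the highest
quality.  All processes of the model (fusion-fission, decay, turnover,
damage) act on this distribution; the readouts defined here summarise it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QualityDistribution",
    "ReadoutRecord",
    "NORM_TOLERANCE",
    "random_initial_distribution",
    "fraction_nonactive",
    "fraction_active",
    "average_quality",
    "deviation_factor",
    "read_distribution_file",
    "write_distribution_file",
]

#: Maximum tolerated deviation of the norm sum(p) from 1 -- the model
#: conserves the norm, so anything beyond round-off indicates a broken
#: operator or an unstable time step.
NORM_TOLERANCE = 1e-7


class InvalidConfigurationError(ValueError):
    """Raised for configuration values that violate a model precondition."""


@dataclass
class QualityDistribution:
    """Probability mass over the quality ladder at one instant.

    Parameters
    ----------
    probs
        Probability per quality state, length ``n_states >= 2``.  Must be
        nonnegative and sum to 1 within :data:`NORM_TOLERANCE`.
    time
        Simulation time in minutes.
    """

    probs: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size < 2:
            raise InvalidConfigurationError(
                "a quality distribution needs at least two states"
            )
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probability mass in quality distribution")
        self.probs = np.where(self.probs < 0.0, 0.0, self.probs)
        err = abs(1.0 - float(self.probs.sum()))
        if err > NORM_TOLERANCE:
            raise ValueError(f"distribution norm deviates from 1 by {err:.3e}")

    @property
    def n_states(self) -> int:
        return self.probs.size

    @property
    def norm_error(self) -> float:
        """Absolute deviation of the norm from 1."""
        return abs(1.0 - float(self.probs.sum()))

    def copy(self) -> "QualityDistribution":
        return QualityDistribution(self.probs.copy(), self.time)


@dataclass
class ReadoutRecord:
    """Scalar readouts of one output time point of a simulation.

    ``fraction_nonactive`` is the mass at state 0, ``fraction_active`` its
    complement; average qualities are means of the state index (all states
    vs. the active states ``l >= 1`` renormalised); ``deviation_factor`` is
    the per-minute L1 change of the distribution; ``renewal_rate`` is the
    biogenesis rate the homeostatic rheostat adapted to at that instant.
    """

    time: float
    fraction_nonactive: float
    fraction_active: float
    avg_quality_all: float
    avg_quality_active: float
    std_quality_active: float
    deviation_factor: float
    norm_error: float
    renewal_rate: float

    FIELDS = (
        "time",
        "fraction_nonactive",
        "fraction_active",
        "avg_quality_all",
        "avg_quality_active",
        "std_quality_active",
        "deviation_factor",
        "norm_error",
        "renewal_rate",
    )


def random_initial_distribution(n_states: int, seed: int) -> QualityDistribution:
    """Random starting distribution: uniform draws per state, normalised.

    Deterministic for a fixed ``seed``.
    """
    if n_states < 2:
        raise InvalidConfigurationError("n_states must be at least 2")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=n_states)
    return QualityDistribution(raw / raw.sum(), time=0.0)


def fraction_nonactive(dist: QualityDistribution) -> float:
    """Mass of fully dysfunctional (state-0, non-fusogenic) mitochondria."""
    return float(dist.probs[0])


def fraction_active(dist: QualityDistribution) -> float:
    """Mass of active mitochondria, summed over states ``l >= 1``."""
    return float(dist.probs[1:].sum())


def average_quality(
    dist: QualityDistribution, active_only: bool = False
) -> tuple[float, float]:
    """Mean and standard deviation of the quality index under ``p``.

    With ``active_only`` the distribution is restricted to ``l >= 1`` and
    renormalised by the active fraction; if no active mass exists the result
    is ``(nan, nan)`` rather than a silent zero.
    """
    levels = np.arange(dist.n_states, dtype=float)
    if active_only:
        weight = float(dist.probs[1:].sum())
        if weight <= 0.0:
            return (math.nan, math.nan)
        p = dist.probs[1:] / weight
        levels = levels[1:]
    else:
        p = dist.probs
    mean = float(np.dot(levels, p))
    var = float(np.dot((levels - mean) ** 2, p))
    return mean, math.sqrt(max(var, 0.0))


def deviation_factor(
    prev: QualityDistribution, curr: QualityDistribution, dt: float
) -> float:
    """Per-minute L1 distance between successive distributions.

    Vanishes exactly at a (flow) equilibrium and fluctuates around a
    constant average under random processes, which makes it the stopping
    criterion of the integrator.
    """
    if prev.n_states != curr.n_states:
        raise ValueError("distributions live on different state spaces")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.abs(curr.probs - prev.probs).sum()) / dt


def read_distribution_file(path, n_states: int | None = None) -> QualityDistribution:
    """Read a two-column (state index, probability) text table.

    Lines starting with ``#`` are comments.  Every state must appear exactly
    once; the index column must enumerate ``0 ... N-1``.
    """
    indices: list[int] = []
    masses: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"expected two columns, got: {raw!r}")
            indices.append(int(parts[0]))
            masses.append(float(parts[1]))
    if sorted(indices) != list(range(len(indices))):
        raise ValueError("state indices must cover 0..N-1 exactly once")
    if n_states is not None and len(indices) != n_states:
        raise ValueError(
            f"file defines {len(indices)} states, configuration expects {n_states}"
        )
    probs = np.empty(len(indices))
    probs[np.array(indices)] = masses
    return QualityDistribution(probs)


def write_distribution_file(path, dist: QualityDistribution) -> None:
    """Write the two-column plain-text representation of a distribution."""
    with open(path, "w") as fh:
        fh.write("# state_index\tprobability\n")
        for l, p in enumerate(dist.probs):
            fh.write(f"{l}\t{p:.17g}\n")
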