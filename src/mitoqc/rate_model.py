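"""Transition-rate model: Hill time courses, pulses, and quality selectivity.

Every process rate factorises as a product ansatz

    rate(t, l)    = schedule(t) * selectivity(l)              (single state)
    rate(t, l, m) = schedule(t) * selectivity(l) * selectivity(m)   (pairwise)

where the schedule is a Hill-form time course (or a rectangular pulse) and
the selectivity is a Hill-form function of the quality state mapping into
[0, 1].  The fusion-fission and biogenesis selectivities vanish at state 0,
encoding that fully dysfunctional mitochondria are non-fusogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .quality_state import InvalidConfigurationError

__all__ = [
    "HillTimeCourse",
    "PulseSchedule",
    "SelectivityProfile",
    "ProcessSpec",
    "PROCESS_IDS",
    "rate_at",
    "selectivity_at",
    "selectivity_values",
    "coupled_infectious_rate",
]

PROCESS_IDS = (
    "fusion_fission",
    "decay",
    "mitophagy",
    "renewal",
    "random_damage",
    "infectious_damage",
)


@dataclass(frozen=True)
class HillTimeCourse:
    """Monotone Hill transition of a rate from ``v_init`` to ``v_final``.

    ``half_time`` (minutes) is the time at which the rate attains the
    midpoint ``(v_init + v_final) / 2``; ``hill_exponent`` sets the
    steepness.  A zero exponent means the rate is constant at ``v_init``.
    """

    v_init: float
    v_final: float
    hill_exponent: float = 0.0
    half_time: float = 1.0

    def __post_init__(self) -> None:
        if self.v_init < 0 or self.v_final < 0:
            raise InvalidConfigurationError("rates must be nonnegative")
        if self.hill_exponent < 0:
            raise InvalidConfigurationError("hill_exponent must be >= 0")
        if self.half_time <= 0:
            raise InvalidConfigurationError("half_time must be positive")

    @property
    def max_rate(self) -> float:
        return max(self.v_init, self.v_final)


@dataclass(frozen=True)
class PulseSchedule:
    """Piecewise-constant rate: ``pulse_rate`` on [start, end), else base."""

    base_rate: float
    pulse_rate: float
    pulse_start: float
    pulse_end: float

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.pulse_rate < 0:
            raise InvalidConfigurationError("rates must be nonnegative")
        if not self.pulse_start < self.pulse_end:
            raise InvalidConfigurationError("pulse_start must precede pulse_end")

    @property
    def max_rate(self) -> float:
        return max(self.base_rate, self.pulse_rate)


Schedule = Union[HillTimeCourse, PulseSchedule]


def rate_at(schedule: Schedule, t: float) -> float:
    """Evaluate a time schedule at ``t`` minutes (``t >= 0``)."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if isinstance(schedule, PulseSchedule):
        if schedule.pulse_start <= t < schedule.pulse_end:
            return schedule.pulse_rate
        return schedule.base_rate
    if schedule.hill_exponent == 0:
        return schedule.v_init
    th = t**schedule.hill_exponent
    tau_h = schedule.half_time**schedule.hill_exponent
    return schedule.v_init + (schedule.v_final - schedule.v_init) * th / (th + tau_h)


@dataclass(frozen=True)
class SelectivityProfile:
    """Hill-form quality dependence of a process rate, valued in [0, 1].

    ``s_low`` is the value at state 0 and ``s_high`` the asymptotic plateau
    toward the top of the ladder; the profile is monotone between them.
    ``zero_at_floor`` forces the value at state 0 to exactly 0 regardless of
    ``s_low`` (non-fusogenic dysfunctional mitochondria).
    """

    s_low: float
    s_high: float
    hill_coefficient: float = 1.0
    hill_exponent: float = 2.0
    zero_at_floor: bool = False

    def __post_init__(self) -> None:
        for v in (self.s_low, self.s_high):
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigurationError("selectivity bounds must lie in [0,1]")
        if self.hill_coefficient <= 0:
            raise InvalidConfigurationError("hill_coefficient must be positive")
        if self.hill_exponent < 0:
            raise InvalidConfigurationError("hill_exponent must be >= 0")


def selectivity_values(profile: SelectivityProfile, n_states: int) -> np.ndarray:
    """Selectivity factor for every state ``0 ... n_states-1`` at once."""
    l = np.arange(n_states, dtype=float)
    if profile.hill_exponent == 0:
        vals = np.full(n_states, 0.5 * (profile.s_low + profile.s_high))
    else:
        lh = l**profile.hill_exponent
        kh = profile.hill_coefficient**profile.hill_exponent
        vals = profile.s_low + (profile.s_high - profile.s_low) * lh / (lh + kh)
    if profile.zero_at_floor:
        vals[0] = 0.0
    return vals


def selectivity_at(profile: SelectivityProfile, l: int, n_states: int) -> float:
    """Selectivity factor of a single quality state."""
    if not 0 <= l < n_states:
        raise IndexError(f"state {l} outside 0..{n_states - 1}")
    return float(selectivity_values(profile, n_states)[l])


@dataclass
class ProcessSpec:
    """Full specification of one process: schedule, selectivity, extras.

    ``extras`` holds process-specific parameters: ``r_max`` (maximal mass
    fraction moved per random-damage event) for random damage; ``rd_limit``
    and ``id_max`` (the coupling of the infectious rate to the concurrent
    random-damage rate) for infectious damage in coupled mode.
    """

    process_id: str
    schedule: Schedule | None = None
    selectivity: SelectivityProfile | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.process_id not in PROCESS_IDS:
            raise InvalidConfigurationError(f"unknown process {self.process_id!r}")
        if self.process_id == "renewal" and self.schedule is not None:
            # the rheostat sets the renewal rate; a free time course is
            # contradictory configuration
            raise InvalidConfigurationError(
                "renewal carries no free time course; its rate is set by the "
                "homeostatic rheostat"
            )

    def rate(self, t: float) -> float:
        if self.schedule is None:
            return 0.0
        return rate_at(self.schedule, t)


def coupled_infectious_rate(
    rd_rate: float, ff_rate: float, id_max: float, rd_limit: float
) -> float:
    """Infectious-damage rate triggered by random damage, capped twice.

    The rate rises linearly with the concurrent random-damage rate up to
    ``id_max`` (reached at ``rd_rate = rd_limit``) and can never exceed the
    fusion-fission rate, which carries the damage.
    """
    if rd_limit <= 0:
        raise InvalidConfigurationError("rd_limit must be positive")
    if min(rd_rate, ff_rate, id_max) < 0:
        raise ValueError("rates must be nonnegative")
    return min(ff_rate, id_max * min(rd_rate / rd_limit, 1.0))
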