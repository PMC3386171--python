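"""Per-process flux operators of the quality-state master equation.

Each operator returns the instantaneous rate of change of the probability
distribution (a "flux vector", per minute per state).  The model is built
from four operators:

* **fusion-fission** -- pairs of mitochondria merge, mix content and split
  again.  In the conserving variant the summed quality of the pair is
  unchanged (``l + m = l' + m'``); the flux is bilinear in the distribution
  and conserves both the norm and the mean quality exactly.  In the
  *infectious* variant the output qualities of randomly chosen events are
  reduced, modelling damage propagated by content mixing.
* **decay** -- a slow one-step-down drift of quality (oxidative damage,
  protein aggregation, hydrolysis).
* **turnover** -- mitophagy removes mass (preferentially low quality) while
  biogenesis re-creates it (preferentially high quality); a homeostatic
  rheostat continuously adapts the biogenesis rate so that the total
  mitochondrial mass never changes.
* **random damage** -- a norm-preserving stochastic reshuffle that moves a
  random fraction of mass from a random higher state to a random lower one;
  applied as an in-step map, not through the flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .quality_state import InvalidConfigurationError, QualityDistribution
from .rate_model import (
    ProcessSpec,
    SelectivityProfile,
    coupled_infectious_rate,
    selectivity_values,
)

__all__ = [
    "FusionFissionEvent",
    "EventList",
    "FusionFissionKernel",
    "enumerate_events",
    "fusion_fission_flux",
    "decay_flux",
    "turnover_flux",
    "random_damage_step",
    "perturb_event_list",
    "assemble_rhs",
    "RhsResult",
    "RheostatDegenerateError",
]

DAMAGE_MODES = ("none", "random", "infectious", "coupled")


class RheostatDegenerateError(RuntimeError):
    """Mitophagy removes mass but no state can receive biogenesis gain."""


@dataclass(frozen=True)
class FusionFissionEvent:
    """One transition ``(l_in, m_in) -> (l_out, m_out)`` of a fusing pair.

    ``quality_deficit`` is the total quality lost by the event; it is 0 for
    quality-conserving events and positive for infectious ones.
    """

    l_in: int
    m_in: int
    l_out: int
    m_out: int

    @property
    def quality_deficit(self) -> int:
        return (self.l_in + self.m_in) - (self.l_out + self.m_out)


@dataclass
class EventList:
    """All fusion-fission transitions of a state space, as index arrays.

    Input pairs are restricted to ``l_in <= m_in`` and outputs to
    ``l_out <= m_out`` to avoid double counting; identity transitions are
    excluded (they carry zero net flux).  ``flag`` records whether the list
    is the quality-conserving enumeration or a damaged (perturbed) copy.
    """

    n_states: int
    l_in: np.ndarray
    m_in: np.ndarray
    l_out: np.ndarray
    m_out: np.ndarray
    flag: str = "conserving"

    def __len__(self) -> int:
        return self.l_in.size

    @property
    def quality_deficit(self) -> np.ndarray:
        return (self.l_in + self.m_in) - (self.l_out + self.m_out)

    def __iter__(self):
        for i in range(len(self)):
            yield FusionFissionEvent(
                int(self.l_in[i]), int(self.m_in[i]),
                int(self.l_out[i]), int(self.m_out[i]),
            )

    def to_table(self):
        """Export as a pandas DataFrame (TSV-friendly) for inspection."""
        import pandas as pd

        return pd.DataFrame(
            {
                "l_in": self.l_in,
                "m_in": self.m_in,
                "l_out": self.l_out,
                "m_out": self.m_out,
                "quality_deficit": self.quality_deficit,
            }
        )


def enumerate_events(n_states: int) -> EventList:
    """Enumerate every quality-conserving fusion-fission transition.

    For each unordered input pair ``(l, m)`` with ``l <= m`` all output
    partitions ``(l', m')`` of the same total ``l + m`` with ``l' <= m'``
    and ``(l', m') != (l, m)`` are listed, in lexicographic order.
    """
    if n_states < 2:
        raise InvalidConfigurationError("n_states must be at least 2")
    li, mi, lo, mo = [], [], [], []
    top = n_states - 1
    for l in range(n_states):
        for m in range(l, n_states):
            q = l + m
            for lp in range(max(0, q - top), q // 2 + 1):
                mp = q - lp
                if (lp, mp) == (l, m):
                    continue
                li.append(l)
                mi.append(m)
                lo.append(lp)
                mo.append(mp)
    return EventList(
        n_states,
        np.asarray(li, dtype=np.intp),
        np.asarray(mi, dtype=np.intp),
        np.asarray(lo, dtype=np.intp),
        np.asarray(mo, dtype=np.intp),
        flag="conserving",
    )


def _event_flux(
    probs: np.ndarray,
    events: EventList,
    schedule_rate: float,
    weights: np.ndarray,
) -> np.ndarray:
    """Bilinear flux summed over an explicit event list.

    Each event carries rate ``a * s(l_in) * s(m_in) * p(l_in) * p(m_in)``,
    charged as a loss at each input slot and a gain at each output slot
    (twice when the two slots coincide).
    """
    n = probs.size
    rate = schedule_rate * weights * probs[events.l_in] * probs[events.m_in]
    both = np.concatenate([rate, rate])
    loss = np.bincount(
        np.concatenate([events.l_in, events.m_in]), weights=both, minlength=n
    )
    gain = np.bincount(
        np.concatenate([events.l_out, events.m_out]), weights=both, minlength=n
    )
    return gain - loss


def fusion_fission_flux(
    dist: QualityDistribution, events: EventList, spec: ProcessSpec, t: float
) -> np.ndarray:
    """Fusion-fission contribution to dp/dt for a given event list.

    For a conserving list the flux sums to zero state-wise *and* leaves the
    mean quality unchanged; for a perturbed list the norm is still conserved
    but quality can only be destroyed.
    """
    if events.n_states != dist.n_states:
        raise ValueError("event list built for a different state space")
    if spec.process_id != "fusion_fission":
        raise ValueError("spec must describe the fusion_fission process")
    s = selectivity_values(spec.selectivity, dist.n_states)
    weights = s[events.l_in] * s[events.m_in]
    return _event_flux(dist.probs, events, spec.rate(t), weights)


class FusionFissionKernel:
    """Grouped O(N^2) evaluation of the conserving fusion-fission flux.

    Algebraically identical to summing over the event list, but events are
    grouped by total quality ``Q = l + m``: the pair-rate totals per ``Q``
    come from a self-convolution of ``q = s * p`` and the gains from a
    precomputed slot-count matrix.  Used by the integrator on large state
    spaces; equality with :func:`fusion_fission_flux` is part of the test
    contract.
    """

    def __init__(self, n_states: int, selectivity: SelectivityProfile):
        self.n_states = n_states
        self.s = selectivity_values(selectivity, n_states)
        n = n_states
        top = n - 1
        # number of ordered-slot partitions of Q and per-pair event counts
        n_partitions = np.array(
            [q // 2 - max(0, q - top) + 1 for q in range(2 * n - 1)]
        )
        # loss matrix: M[l, m] = events spawned by input pair {l, m},
        # doubled on the diagonal because both input slots coincide
        l = np.arange(n)
        qsum = l[:, None] + l[None, :]
        m_mat = (n_partitions[qsum] - 1).astype(float)
        m_mat[np.diag_indices(n)] *= 2.0
        self._loss_mat = m_mat
        # gain slot counts: G[l', Q] = occurrences of l' among the output
        # slots of all partitions of Q (2 when l' is the symmetric half)
        g = np.zeros((n, 2 * n - 1))
        for lp in range(n):
            for q in range(2 * n - 1):
                partner = q - lp
                if 0 <= partner <= top:
                    g[lp, q] = 2.0 if partner == lp else 1.0
        self._gain_mat = g

    def flux(self, probs: np.ndarray, schedule_rate: float) -> np.ndarray:
        q = self.s * probs
        total = q.sum()
        conv = np.convolve(q, q)
        even = np.zeros_like(conv)
        even[::2] = q * q
        pair_rate = 0.5 * (conv + even)  # sum of q_l q_m over unordered pairs
        gain = self._gain_mat @ pair_rate - q * (total + q)
        loss = q * (self._loss_mat @ q)
        return schedule_rate * (gain - loss)


def decay_flux(
    dist: QualityDistribution, spec: ProcessSpec, t: float
) -> np.ndarray:
    """One-step-down quality drift: gradual loss of molecular integrity."""
    if spec.process_id != "decay":
        raise ValueError("spec must describe the decay process")
    s = selectivity_values(spec.selectivity, dist.n_states)
    out = spec.rate(t) * s * dist.probs
    out[0] = 0.0  # the floor state cannot decay further
    flux = np.empty_like(out)
    flux[:-1] = out[1:]
    flux[-1] = 0.0
    return flux - out


def turnover_flux(
    dist: QualityDistribution,
    mitophagy_spec: ProcessSpec,
    renewal_selectivity: SelectivityProfile,
    t: float,
) -> tuple[np.ndarray, float]:
    """Mitophagy loss balanced by biogenesis gain under homeostasis.

    Mass removed at each state at rate ``gamma(t) * s_mito(l) * p(l)`` is
    re-created across states proportionally to ``s_ren(l) * p(l)``; the
    returned renewal rate is the rheostat value that makes total gain equal
    total loss at this instant.
    """
    if mitophagy_spec.process_id != "mitophagy":
        raise ValueError("spec must describe the mitophagy process")
    s_mito = selectivity_values(mitophagy_spec.selectivity, dist.n_states)
    loss = mitophagy_spec.rate(t) * s_mito * dist.probs
    total_loss = float(loss.sum())
    weight = selectivity_values(renewal_selectivity, dist.n_states) * dist.probs
    total_weight = float(weight.sum())
    if total_loss <= 0.0:
        return -loss, 0.0
    if total_weight <= 0.0:
        raise RheostatDegenerateError(
            "mitophagy removes mass but the renewal selectivity gives every "
            "populated state zero weight; homeostasis is impossible"
        )
    renewal_rate = total_loss / total_weight
    return renewal_rate * weight - loss, renewal_rate


def random_damage_step(
    dist: QualityDistribution,
    rd_rate: float,
    r_max: float,
    dt: float,
    rng: np.random.Generator,
) -> QualityDistribution:
    """Apply one time step of random molecular damage (e.g. ROS hits).

    The number of damage events is Poisson with mean ``rd_rate * dt``.  Each
    event picks a source state ``l`` uniformly from ``1..N-1``, a sink
    ``l' < l`` uniformly, and moves a uniform random fraction in
    ``(0, r_max]`` of the source mass down to the sink.  The norm is
    conserved by construction.
    """
    if not 0.0 < r_max <= 1.0:
        raise InvalidConfigurationError("r_max must lie in (0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    probs = dist.probs.copy()
    n = probs.size
    n_events = rng.poisson(rd_rate * dt)
    for _ in range(n_events):
        l = int(rng.integers(1, n))
        sink = int(rng.integers(0, l))
        fraction = r_max * (1.0 - rng.random())  # uniform in (0, r_max]
        moved = fraction * probs[l]
        probs[l] -= moved
        probs[sink] += moved
    return QualityDistribution(probs, dist.time)


def perturb_event_list(
    events: EventList,
    id_rate: float,
    ff_rate: float,
    dt: float,
    rng: np.random.Generator,
    eps_max: int | None = None,
) -> EventList:
    """Replace conserving events by damaged copies (infectious damage).

    Each event is independently damaged with probability ``id_rate /
    ff_rate`` -- the fraction of fusion-fission traffic that propagates
    damage.  A damaged copy reduces each output by an independent uniform
    integer in ``[0, min(eps_max, output)]`` (``eps_max=None`` allows the
    full admissible range), so outputs stay nonnegative and total quality
    can only fall.  The list must be regenerated every time step.
    """
    if id_rate < 0 or ff_rate < 0:
        raise ValueError("rates must be nonnegative")
    if id_rate > ff_rate:
        raise ValueError(
            "infectious-damage rate exceeds the fusion-fission rate that "
            "carries it"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    prob = id_rate / ff_rate if ff_rate > 0 else 0.0
    if prob == 0.0:
        return EventList(
            events.n_states, events.l_in, events.m_in,
            events.l_out, events.m_out, flag="conserving",
        )
    l_out = events.l_out.copy()
    m_out = events.m_out.copy()
    mask = rng.random(len(events)) < prob
    if mask.any():
        hi1 = l_out[mask]
        hi2 = m_out[mask]
        if eps_max is not None:
            hi1 = np.minimum(hi1, eps_max)
            hi2 = np.minimum(hi2, eps_max)
        eps1 = rng.integers(0, hi1 + 1)
        eps2 = rng.integers(0, hi2 + 1)
        a = l_out[mask] - eps1
        b = m_out[mask] - eps2
        l_out[mask] = np.minimum(a, b)
        m_out[mask] = np.maximum(a, b)
    return EventList(
        events.n_states, events.l_in, events.m_in, l_out, m_out, flag="perturbed"
    )


def sample_perturbation(
    events: EventList,
    prob: float,
    rng: np.random.Generator,
    eps_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one step's damaged events: indices and damaged (sorted) outputs.

    Sampling a Binomial count and then a uniform subset is equivalent to
    independent Bernoulli damage per event but touches only the damaged
    ones, which the integrator exploits when the damaged fraction is small.
    """
    n_events = len(events)
    if prob <= 0:
        k = 0
    elif prob * n_events <= 200:
        k = rng.binomial(n_events, prob)
    else:
        # dense regime: per-event Bernoulli mask is cheaper than subset draw
        idx = np.flatnonzero(rng.random(n_events) < prob)
        k = -1
    if k == 0:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty, empty
    if k > 0:
        idx = rng.choice(n_events, size=k, replace=False)
    hi1 = events.l_out[idx]
    hi2 = events.m_out[idx]
    if eps_max is not None:
        hi1 = np.minimum(hi1, eps_max)
        hi2 = np.minimum(hi2, eps_max)
    a = events.l_out[idx] - rng.integers(0, hi1 + 1)
    b = events.m_out[idx] - rng.integers(0, hi2 + 1)
    return idx, np.minimum(a, b), np.maximum(a, b)


def perturbation_flux_correction(
    events: EventList,
    idx: np.ndarray,
    new_lo: np.ndarray,
    new_hi: np.ndarray,
    probs: np.ndarray,
    selectivity: np.ndarray,
    schedule_rate: float,
) -> np.ndarray:
    """Flux difference from damaging the listed events' outputs.

    Adding this to the conserving flux reproduces the flux of the perturbed
    event list exactly: damaged events keep their input rate, only their
    gain moves from the conserving outputs to the damaged ones.
    """
    n = probs.size
    rate = (
        schedule_rate
        * selectivity[events.l_in[idx]]
        * selectivity[events.m_in[idx]]
        * probs[events.l_in[idx]]
        * probs[events.m_in[idx]]
    )
    both = np.concatenate([rate, rate])
    corr = np.bincount(
        np.concatenate([new_lo, new_hi]), weights=both, minlength=n
    )
    corr -= np.bincount(
        np.concatenate([events.l_out[idx], events.m_out[idx]]),
        weights=both,
        minlength=n,
    )
    return corr


class RhsResult(NamedTuple):
    flux: np.ndarray
    renewal_rate: float
    events_used: EventList


def effective_infectious_rate(
    specs: dict[str, ProcessSpec], t: float, damage_mode: str
) -> float:
    """Infectious-damage rate at time ``t`` for the given mode.

    In ``infectious`` mode the configured Hill course is capped by the
    concurrent fusion-fission rate; in ``coupled`` mode the rate is slaved
    to the concurrent random-damage rate (and still capped).
    """
    ff_rate = specs["fusion_fission"].rate(t)
    id_spec = specs["infectious_damage"]
    if damage_mode == "coupled":
        rd_rate = specs["random_damage"].rate(t)
        return coupled_infectious_rate(
            rd_rate,
            ff_rate,
            id_spec.extras["id_max"],
            id_spec.extras["rd_limit"],
        )
    return min(id_spec.rate(t), ff_rate)


def assemble_rhs(
    dist: QualityDistribution,
    events: EventList,
    specs: dict[str, ProcessSpec],
    t: float,
    damage_mode: str = "none",
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
) -> RhsResult:
    """Sum the flux operators active in the given damage mode.

    Random damage is *not* part of the flux: it is applied as a separate
    norm-preserving reshuffle within the integration step.  In infectious
    and coupled modes the fusion-fission flux is evaluated on a freshly
    perturbed event list, which requires ``rng``.
    """
    if damage_mode not in DAMAGE_MODES:
        raise InvalidConfigurationError(f"unknown damage mode {damage_mode!r}")
    required = ["fusion_fission", "decay", "mitophagy", "renewal"]
    if damage_mode in ("random", "coupled"):
        required.append("random_damage")
    if damage_mode in ("infectious", "coupled"):
        required.append("infectious_damage")
    for pid in required:
        if pid not in specs:
            raise InvalidConfigurationError(
                f"damage mode {damage_mode!r} requires a spec for {pid!r}"
            )
    events_used = events
    if damage_mode in ("infectious", "coupled"):
        if rng is None:
            raise InvalidConfigurationError(
                "infectious damage needs a random generator to perturb the "
                "event list"
            )
        ff_rate = specs["fusion_fission"].rate(t)
        id_rate = effective_infectious_rate(specs, t, damage_mode)
        events_used = perturb_event_list(
            events, id_rate, ff_rate, dt, rng,
            eps_max=specs["infectious_damage"].extras.get("eps_max"),
        )
    flux = fusion_fission_flux(dist, events_used, specs["fusion_fission"], t)
    flux += decay_flux(dist, specs["decay"], t)
    turnover, renewal_rate = turnover_flux(
        dist, specs["mitophagy"], specs["renewal"].selectivity, t
    )
    flux += turnover
    return RhsResult(flux, renewal_rate, events_used)
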