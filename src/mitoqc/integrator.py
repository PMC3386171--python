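"""Forward-Euler time integration of the quality-state master equation.

The integrator advances ``p(l, t)`` with a fixed time step, monitors the
norm (which the model conserves exactly, so norm drift measures numerical
stability), applies the in-step random-damage reshuffle when active, and
records scalar readouts on a regular output grid.  Equilibrium is detected
through the deviation factor: it must fall below a tolerance in
deterministic modes, or its windowed average must stop changing in
stochastic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quality_state import (
    InvalidConfigurationError,
    NORM_TOLERANCE,
    QualityDistribution,
    ReadoutRecord,
    average_quality,
    fraction_active,
    fraction_nonactive,
    random_initial_distribution,
    read_distribution_file,
)
from .rate_model import ProcessSpec, selectivity_values
from .operators import (
    DAMAGE_MODES,
    EventList,
    FusionFissionKernel,
    assemble_rhs,
    effective_infectious_rate,
    enumerate_events,
    perturbation_flux_correction,
    random_damage_step,
    sample_perturbation,
    turnover_flux,
)

__all__ = ["SimulationConfig", "SimulationReport", "IntegrationInstabilityError", "step", "run"]

#: Largest negative excursion of a single mass value that is treated as
#: round-off and clamped; anything worse means the time step is too large.
NEGATIVITY_TOLERANCE = 1e-12


class IntegrationInstabilityError(RuntimeError):
    """Norm drift or negativity beyond tolerance -- reduce the time step."""


@dataclass
class SimulationConfig:
    """Complete specification of one master-equation run.

    ``initial`` selects the starting distribution: ``None`` draws a seeded
    random distribution, a string is read as a two-column text file, an
    array is used directly.  ``stop_at_equilibrium`` ends the run early once
    the equilibrium criterion holds; otherwise integration continues to
    ``t_end``.
    """

    n_states: int = 50
    dt: float = 0.1
    t_end: float = 20000.0
    output_every: float = 50.0
    specs: dict[str, ProcessSpec] = field(default_factory=dict)
    damage_mode: str = "none"
    seed: int = 0
    equilibrium_tolerance: float = 1e-9
    initial: object = None
    stop_at_equilibrium: bool = False
    stochastic_window: int = 500
    stochastic_rel_change: float = 0.05
    record_distributions: bool = False

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise InvalidConfigurationError("n_states must be at least 2")
        if self.dt <= 0:
            raise InvalidConfigurationError("dt must be positive")
        if self.t_end <= 0:
            raise InvalidConfigurationError("t_end must be positive")
        if self.damage_mode not in DAMAGE_MODES:
            raise InvalidConfigurationError(
                f"damage_mode must be one of {DAMAGE_MODES}"
            )
        max_rate = 0.0
        for spec in self.specs.values():
            if spec.schedule is not None:
                max_rate = max(max_rate, spec.schedule.max_rate)
        if max_rate > 0 and self.dt >= 1.0 / max_rate:
            raise InvalidConfigurationError(
                f"dt={self.dt} must be smaller than the inverse of the "
                f"largest rate (1/{max_rate} min)"
            )

    @property
    def is_stochastic(self) -> bool:
        return self.damage_mode != "none"

    def initial_distribution(self) -> QualityDistribution:
        if self.initial is None:
            return random_initial_distribution(self.n_states, self.seed)
        if isinstance(self.initial, str):
            return read_distribution_file(self.initial, self.n_states)
        if isinstance(self.initial, QualityDistribution):
            return QualityDistribution(self.initial.probs.copy(), 0.0)
        return QualityDistribution(np.asarray(self.initial, dtype=float), 0.0)


@dataclass
class SimulationReport:
    """Recorded outcome of a run: readout series and final state."""

    records: pd.DataFrame
    final: QualityDistribution
    max_norm_error: float
    equilibrium_reached: bool
    equilibrium_time: float | None
    config: SimulationConfig
    #: distribution snapshots at the output times (only when
    #: ``config.record_distributions``), shape (n_outputs, n_states)
    distributions: np.ndarray | None = None

    def last(self) -> pd.Series:
        return self.records.iloc[-1]

    def summary(self) -> dict:
        last = self.last()
        return {
            "t_final": float(last["time"]),
            "fraction_active": float(last["fraction_active"]),
            "fraction_nonactive": float(last["fraction_nonactive"]),
            "avg_quality_all": float(last["avg_quality_all"]),
            "avg_quality_active": float(last["avg_quality_active"]),
            "std_quality_active": float(last["std_quality_active"]),
            "renewal_rate": float(last["renewal_rate"]),
            "max_norm_error": self.max_norm_error,
            "equilibrium_reached": self.equilibrium_reached,
            "equilibrium_time": self.equilibrium_time,
        }


def _clamp(probs: np.ndarray) -> np.ndarray:
    """Clamp round-off negativity to zero, redistributing proportionally."""
    low = probs.min()
    if low >= 0.0:
        return probs
    if low < -NEGATIVITY_TOLERANCE:
        raise IntegrationInstabilityError(
            f"probability mass driven to {low:.3e} (< -{NEGATIVITY_TOLERANCE}); "
            "the time step is too large for the configured rates"
        )
    clipped = np.clip(probs, 0.0, None)
    return clipped * (probs.sum() / clipped.sum())


def step(
    dist: QualityDistribution,
    config: SimulationConfig,
    events: EventList,
    t: float,
    rng: np.random.Generator | None = None,
) -> QualityDistribution:
    """One forward-Euler step ``p <- p + dt * rhs`` plus in-step damage.

    Reference entry point for single steps; :func:`run` uses an equivalent
    fused loop.  Raises :class:`IntegrationInstabilityError` if the norm
    drifts beyond tolerance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rhs = assemble_rhs(
        dist, events, config.specs, t, config.damage_mode, rng, config.dt
    )
    probs = _clamp(dist.probs + config.dt * rhs.flux)
    out = QualityDistribution(probs, t + config.dt)
    if config.damage_mode in ("random", "coupled"):
        rd = config.specs["random_damage"]
        out = random_damage_step(
            out, rd.rate(t), rd.extras.get("r_max", 0.5), config.dt, rng
        )
    if out.norm_error > NORM_TOLERANCE:
        raise IntegrationInstabilityError(
            f"norm error {out.norm_error:.3e} exceeds {NORM_TOLERANCE}; "
            "reduce dt"
        )
    return out


def _readout(
    dist: QualityDistribution, dev: float, renewal_rate: float
) -> ReadoutRecord:
    mean_all, _ = average_quality(dist, active_only=False)
    mean_act, std_act = average_quality(dist, active_only=True)
    return ReadoutRecord(
        time=dist.time,
        fraction_nonactive=fraction_nonactive(dist),
        fraction_active=fraction_active(dist),
        avg_quality_all=mean_all,
        avg_quality_active=mean_act,
        std_quality_active=std_act,
        deviation_factor=dev,
        norm_error=dist.norm_error,
        renewal_rate=renewal_rate,
    )


def run(config: SimulationConfig) -> SimulationReport:
    """Integrate the master equation and record the readout time series.

    Fully reproducible from ``(config, seed)``.  The deviation factor is
    evaluated every step; in deterministic mode equilibrium is declared once
    it drops below ``equilibrium_tolerance``, in stochastic modes once its
    average over a ``stochastic_window``-step window changes by less than
    ``stochastic_rel_change`` between consecutive windows.
    """
    rng = np.random.default_rng(config.seed)
    dist = config.initial_distribution()
    events = enumerate_events(config.n_states)
    specs = config.specs
    ff = specs["fusion_fission"]
    kernel = FusionFissionKernel(config.n_states, ff.selectivity)
    perturbed_mode = config.damage_mode in ("infectious", "coupled")
    random_mode = config.damage_mode in ("random", "coupled")
    rd_spec = specs.get("random_damage")
    s_decay = selectivity_values(specs["decay"].selectivity, config.n_states)
    s_mito = selectivity_values(specs["mitophagy"].selectivity, config.n_states)
    s_ren = selectivity_values(specs["renewal"].selectivity, config.n_states)
    decay = specs["decay"]
    mitophagy = specs["mitophagy"]
    eps_max = None
    if perturbed_mode:
        eps_max = specs["infectious_damage"].extras.get("eps_max")
        # dense-regime precomputation: per-event admissible damage ranges
        # and input-pair selectivity products never change
        hi1 = events.l_out
        hi2 = events.m_out
        if eps_max is not None:
            hi1 = np.minimum(hi1, eps_max)
            hi2 = np.minimum(hi2, eps_max)
        hi1p1 = (hi1 + 1).astype(float)
        hi2p1 = (hi2 + 1).astype(float)
        s_ff = kernel.s
        w_in = s_ff[events.l_in] * s_ff[events.m_in]
        n_events = len(events)
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    out_stride = max(1, int(round(config.output_every / dt)))

    # first record: renewal rate at t=0 from the rheostat balance
    _, renewal0 = turnover_flux(
        dist, specs["mitophagy"], specs["renewal"].selectivity, 0.0
    )
    records = [_readout(dist, np.nan, renewal0)]
    snapshots = [dist.probs.copy()] if config.record_distributions else None
    max_norm_error = dist.norm_error
    equilibrium_reached = False
    equilibrium_time: float | None = None
    window_sum = 0.0
    prev_window_mean: float | None = None

    p = dist.probs.copy()
    for i in range(n_steps):
        t = i * dt
        ff_rate = ff.rate(t)
        if perturbed_mode:
            id_rate = effective_infectious_rate(specs, t, config.damage_mode)
            prob = id_rate / ff_rate if ff_rate > 0 else 0.0
        if perturbed_mode and prob * n_events > 200:
            # dense regime: damage (or not) every event in one vector pass
            eps1 = np.floor(rng.random(n_events) * hi1p1).astype(np.intp)
            eps2 = np.floor(rng.random(n_events) * hi2p1).astype(np.intp)
            if prob < 1.0:
                undamaged = rng.random(n_events) >= prob
                eps1[undamaged] = 0
                eps2[undamaged] = 0
            a = events.l_out - eps1
            b = events.m_out - eps2
            rate = ff_rate * w_in * p[events.l_in] * p[events.m_in]
            gain = np.bincount(
                np.minimum(a, b), weights=rate, minlength=config.n_states
            )
            gain += np.bincount(
                np.maximum(a, b), weights=rate, minlength=config.n_states
            )
            loss = np.bincount(events.l_in, weights=rate, minlength=config.n_states)
            loss += np.bincount(events.m_in, weights=rate, minlength=config.n_states)
            flux = gain - loss
        else:
            flux = kernel.flux(p, ff_rate)
            if perturbed_mode and prob > 0:
                idx, new_lo, new_hi = sample_perturbation(
                    events, prob, rng, eps_max=eps_max
                )
                if idx.size:
                    flux += perturbation_flux_correction(
                        events, idx, new_lo, new_hi, p, kernel.s, ff_rate
                    )
        # decay (one-step-down drift)
        down = decay.rate(t) * s_decay * p
        down[0] = 0.0
        flux[:-1] += down[1:]
        flux -= down
        # turnover with homeostatic rheostat
        loss = mitophagy.rate(t) * s_mito * p
        total_loss = loss.sum()
        weight = s_ren * p
        total_weight = weight.sum()
        if total_loss > 0.0:
            if total_weight <= 0.0:
                raise RuntimeError(
                    "homeostasis failed mid-run: no state can receive "
                    "biogenesis gain"
                ) from None
            renewal_rate = total_loss / total_weight
            flux += renewal_rate * weight - loss
        else:
            renewal_rate = 0.0
            flux -= loss
        p_new = _clamp(p + dt * flux)
        t_new = t + dt
        if random_mode:
            d = QualityDistribution.__new__(QualityDistribution)
            d.probs = p_new
            d.time = t_new
            d = random_damage_step(
                d, rd_spec.rate(t), rd_spec.extras.get("r_max", 0.5), dt, rng
            )
            p_new = d.probs
        norm_error = abs(1.0 - p_new.sum())
        if norm_error > NORM_TOLERANCE:
            raise IntegrationInstabilityError(
                f"norm error {norm_error:.3e} at t={t_new:.1f} min exceeds "
                f"{NORM_TOLERANCE}; reduce dt"
            )
        max_norm_error = max(max_norm_error, norm_error)
        dev = np.abs(p_new - p).sum() / dt
        p = p_new

        if not equilibrium_reached:
            if config.is_stochastic:
                window_sum += dev
                if (i + 1) % config.stochastic_window == 0:
                    mean = window_sum / config.stochastic_window
                    window_sum = 0.0
                    if prev_window_mean is not None and prev_window_mean > 0:
                        if (
                            abs(mean - prev_window_mean)
                            < config.stochastic_rel_change * prev_window_mean
                        ):
                            equilibrium_reached = True
                            equilibrium_time = t_new
                    prev_window_mean = mean
            elif dev < config.equilibrium_tolerance:
                equilibrium_reached = True
                equilibrium_time = t_new

        last_step = i == n_steps - 1
        stopping = (
            equilibrium_reached
            and config.stop_at_equilibrium
            and equilibrium_time == t_new
        )
        if (i + 1) % out_stride == 0 or last_step or stopping:
            dist_out = QualityDistribution(p.copy(), t_new)
            records.append(_readout(dist_out, dev, renewal_rate))
            if snapshots is not None:
                snapshots.append(p.copy())
        if stopping:
            break

    final = QualityDistribution(p.copy(), records[-1].time)
    frame = pd.DataFrame(
        [[getattr(r, f) for f in ReadoutRecord.FIELDS] for r in records],
        columns=ReadoutRecord.FIELDS,
    )
    return SimulationReport(
        records=frame,
        final=final,
        max_norm_error=max_norm_error,
        equilibrium_reached=equilibrium_reached,
        equilibrium_time=equilibrium_time,
        config=config,
        distributions=np.asarray(snapshots) if snapshots is not None else None,
    )
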