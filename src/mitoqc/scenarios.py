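"""Pre-packaged simulation experiments.

Each driver reproduces one in-silico experiment of the model study:

* :func:`run_reference` -- the undamaged mitochondrial life cycle, run from
  a random start to flow equilibrium.
* :func:`run_damage` -- random or infectious molecular damage switched on
  from the reference equilibrium (optionally as a time pulse).
* :func:`run_aging` -- age-dependent deceleration of fusion-fission cycles,
  compared against the constant-rate counterpart, with and without damage.
* :func:`run_mida` -- the 'mitochondrial infectious damage adaptation'
  life-span comparison: random damage triggering infectious damage, with
  constant vs decelerating fusion-fission, and a survival threshold that
  converts the readout trace into a life span.
* :func:`run_knockout` -- reference dynamics with process groups removed.

Every driver is a pure function of ``(configuration, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import default_config
from .integrator import SimulationConfig, SimulationReport, run
from .quality_state import InvalidConfigurationError
from .rate_model import HillTimeCourse

__all__ = [
    "ScenarioResult",
    "MidaOutcome",
    "decelerating_schedule",
    "run_reference",
    "run_damage",
    "run_aging",
    "run_mida",
    "run_knockout",
]

#: Horizon (minutes) of the damage-phase scenarios; the damage rates plateau
#: after a few half-times (2000 min) and the readouts are quasi-stationary
#: well before this time.
DAMAGE_T_END = 20000.0

#: Deceleration endpoint as a fraction of the initial fusion-fission rate.
DECEL_FRACTION = 0.04
DECEL_HALF_TIME = 2000.0
DECEL_EXPONENT = 4.0


@dataclass
class ScenarioResult:
    """Named bundle of one or more runs plus derived comparatives."""

    name: str
    reports: dict[str, SimulationReport]
    comparatives: dict = field(default_factory=dict)


@dataclass
class MidaOutcome:
    """Life-span comparison between decelerating and constant dynamics.

    Life span is the first time the chosen readout falls below the survival
    threshold (linear interpolation between output points); ``None`` with
    the corresponding ``censored`` flag if the threshold is never crossed
    within the horizon.
    """

    survival_threshold: float
    readout: str
    lifespan_mida: float | None
    lifespan_constant: float | None
    extension: float | None
    censored_mida: bool = False
    censored_constant: bool = False


def decelerating_schedule(v_init: float) -> HillTimeCourse:
    """Age-dependent fusion-fission deceleration: Hill decay to 4%.

    The decelerated rate must fall below the infectious-damage plateau for
    the fusion-fission cap on infectious damage to become active, which is
    the mechanism behind the deceleration benefit.
    """
    return HillTimeCourse(
        v_init, DECEL_FRACTION * v_init, DECEL_EXPONENT, DECEL_HALF_TIME
    )


_reference_cache: dict[tuple, SimulationReport] = {}


def run_reference(seed: int = 0, config: SimulationConfig | None = None) -> ScenarioResult:
    """Reference life cycle: fusion-fission + decay + turnover, no damage.

    Runs from a seeded random initial distribution until the deviation
    factor drops below tolerance (flow equilibrium).  Results are cached per
    seed so downstream scenarios can start from the equilibrium without
    recomputing it.
    """
    if config is None:
        key = ("default", seed)
        if key in _reference_cache:
            report = _reference_cache[key]
        else:
            report = run(
                default_config(
                    seed=seed,
                    t_end=160000.0,
                    equilibrium_tolerance=5e-9,
                    stop_at_equilibrium=True,
                    output_every=500.0,
                )
            )
            _reference_cache[key] = report
    else:
        report = run(config)
    return ScenarioResult("reference", {"reference": report})


def _damage_overrides(mode: str, pulsed: bool) -> dict:
    if pulsed:
        base = default_config()
        procs = {}
        for pid in ("random_damage", "infectious_damage"):
            spec = base.specs[pid]
            plateau = spec.schedule.max_rate
            procs[pid] = {
                "schedule": {
                    "type": "pulse",
                    "base_rate": 0.0,
                    "pulse_rate": plateau,
                    "pulse_start": 2000.0,
                    "pulse_end": 8000.0,
                }
            }
        return {"processes": procs}
    return {}


def run_damage(
    mode: str,
    pulsed: bool = False,
    seed: int = 0,
    reference: SimulationReport | None = None,
    t_end: float = DAMAGE_T_END,
) -> ScenarioResult:
    """Molecular damage switched on from the reference equilibrium.

    ``mode`` is ``random`` (ROS-like reshuffle) or ``infectious``
    (conservation-violating fusion-fission events); ``pulsed`` replaces the
    Hill ramp of the damage rate by a rectangular pulse.  Comparatives hold
    the shifts of the active fraction and active average quality relative to
    the reference equilibrium.
    """
    if mode not in ("random", "infectious"):
        raise InvalidConfigurationError("damage mode must be random or infectious")
    if reference is None:
        reference = run_reference(seed).reports["reference"]
    cfg = default_config(
        damage_mode=mode, seed=seed, t_end=t_end, output_every=100.0,
        **_damage_overrides(mode, pulsed),
    )
    cfg.initial = reference.final
    report = run(cfg)
    ref_last = reference.last()
    last = report.last()
    comparatives = {
        "delta_fraction_nonactive": float(
            last["fraction_nonactive"] - ref_last["fraction_nonactive"]
        ),
        "delta_fraction_active": float(
            last["fraction_active"] - ref_last["fraction_active"]
        ),
        "delta_avg_quality_active": float(
            last["avg_quality_active"] - ref_last["avg_quality_active"]
        ),
    }
    name = f"damage_{mode}" + ("_pulsed" if pulsed else "")
    return ScenarioResult(name, {mode: report, "reference": reference}, comparatives)


def run_aging(
    mode: str = "none",
    seed: int = 0,
    reference: SimulationReport | None = None,
    t_end: float = DAMAGE_T_END,
) -> ScenarioResult:
    """Decelerating vs constant fusion-fission under a given damage mode.

    Both runs start from the reference equilibrium; the decelerating run
    replaces the fusion-fission time course by :func:`decelerating_schedule`.
    """
    if mode not in ("none", "random", "infectious", "coupled"):
        raise InvalidConfigurationError(f"unknown aging mode {mode!r}")
    if reference is None:
        reference = run_reference(seed).reports["reference"]
    reports = {}
    for label, decelerate in (("constant", False), ("decelerating", True)):
        cfg = default_config(
            damage_mode=mode, seed=seed, t_end=t_end, output_every=100.0
        )
        if decelerate:
            ff = cfg.specs["fusion_fission"]
            ff.schedule = decelerating_schedule(ff.schedule.v_init)
        cfg.initial = reference.final
        reports[label] = run(cfg)
    const = reports["constant"].last()
    decel = reports["decelerating"].last()
    comparatives = {
        "delta_fraction_active": float(
            decel["fraction_active"] - const["fraction_active"]
        ),
        "delta_avg_quality_active": float(
            decel["avg_quality_active"] - const["avg_quality_active"]
        ),
    }
    reports["reference"] = reference
    return ScenarioResult(f"aging_{mode}", reports, comparatives)


def _first_crossing(report: SimulationReport, readout: str, threshold: float):
    """Time of the first downward crossing of ``threshold``, interpolated."""
    times = report.records["time"].to_numpy()
    values = report.records[readout].to_numpy()
    below = values < threshold
    if not below.any():
        return None
    i = int(below.argmax())
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v0 == v1:
        return float(t1)
    return float(t0 + (t1 - t0) * (v0 - threshold) / (v0 - v1))


def run_mida(
    threshold: float | None = None,
    readout: str = "fraction_active",
    seed: int = 0,
    reference: SimulationReport | None = None,
    t_end: float = DAMAGE_T_END,
) -> ScenarioResult:
    """MIDA life-span experiment: coupled damage, constant vs decelerating.

    Random molecular damage triggers infectious damage (coupled mode); the
    survival threshold defaults to 60% of the reference-equilibrium value of
    the chosen readout.  The all-states average quality is also accepted as
    ``readout`` but is dominated by the dysfunctional state-0 peak of the
    double-peaked distribution, which can invert the comparison.
    """
    if reference is None:
        reference = run_reference(seed).reports["reference"]
    aging = run_aging("coupled", seed=seed, reference=reference, t_end=t_end)
    if threshold is None:
        threshold = 0.6 * float(reference.last()[readout])
    lifespan_const = _first_crossing(aging.reports["constant"], readout, threshold)
    lifespan_mida = _first_crossing(
        aging.reports["decelerating"], readout, threshold
    )
    extension = None
    if lifespan_const is not None and lifespan_mida is not None:
        extension = lifespan_mida - lifespan_const
    outcome = MidaOutcome(
        survival_threshold=threshold,
        readout=readout,
        lifespan_mida=lifespan_mida,
        lifespan_constant=lifespan_const,
        extension=extension,
        censored_mida=lifespan_mida is None,
        censored_constant=lifespan_const is None,
    )
    return ScenarioResult(
        "mida",
        aging.reports,
        {"outcome": outcome, **aging.comparatives},
    )


_KNOCKOUT_GROUPS = {"fusion_fission", "decay", "mitophagy"}


def run_knockout(
    disabled: set[str],
    seed: int = 0,
    t_end: float = DAMAGE_T_END,
) -> ScenarioResult:
    """Reference dynamics with the named process groups switched off.

    ``mitophagy`` disables mitophagy and biogenesis jointly (they are paired
    by homeostasis); asking to disable ``renewal`` alone is a configuration
    error.
    """
    disabled = set(disabled)
    if "renewal" in disabled:
        raise InvalidConfigurationError(
            "renewal cannot be disabled alone; disable 'mitophagy' to remove "
            "the mitophagy/biogenesis pair"
        )
    unknown = disabled - _KNOCKOUT_GROUPS
    if unknown:
        raise InvalidConfigurationError(
            f"unknown knockout groups {sorted(unknown)}; expected subset of "
            f"{sorted(_KNOCKOUT_GROUPS)}"
        )
    procs = {
        pid: {"schedule": {"type": "hill", "v_init": 0.0, "v_final": 0.0,
                           "hill_exponent": 0, "half_time": 1.0}}
        for pid in disabled
    }
    cfg = default_config(
        seed=seed, t_end=t_end, output_every=100.0, processes=procs
    )
    report = run(cfg)
    return ScenarioResult(
        "knockout_" + "+".join(sorted(disabled)) if disabled else "knockout_none",
        {"knockout": report},
        {"disabled": sorted(disabled)},
    )
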