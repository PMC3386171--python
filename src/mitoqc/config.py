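"""YAML scenario configuration: loading, validation, defaults.

The entire default parameter set lives in ``data/reference.yaml``; nothing
is hard-coded.  Validation errors name the offending key.
"""

from __future__ import annotations

import copy
from importlib import resources

import yaml

from .quality_state import InvalidConfigurationError
from .rate_model import (
    HillTimeCourse,
    PROCESS_IDS,
    ProcessSpec,
    PulseSchedule,
    SelectivityProfile,
)
from .integrator import SimulationConfig

__all__ = ["load_config", "default_config", "config_to_dict"]

_SCHEDULE_KEYS = {
    "hill": {"v_init", "v_final", "hill_exponent", "half_time"},
    "pulse": {"base_rate", "pulse_rate", "pulse_start", "pulse_end"},
}


def _build_schedule(block: dict, where: str):
    if not isinstance(block, dict) or "type" not in block:
        raise InvalidConfigurationError(f"{where}: schedule needs a 'type' key")
    kind = block["type"]
    params = {k: v for k, v in block.items() if k != "type"}
    if kind == "hill":
        cls = HillTimeCourse
    elif kind == "pulse":
        cls = PulseSchedule
    else:
        raise InvalidConfigurationError(
            f"{where}.type: unknown schedule type {kind!r} (hill or pulse)"
        )
    unknown = set(params) - _SCHEDULE_KEYS[kind]
    if unknown:
        raise InvalidConfigurationError(
            f"{where}: unknown schedule keys {sorted(unknown)}"
        )
    try:
        return cls(**params)
    except (TypeError, InvalidConfigurationError) as exc:
        raise InvalidConfigurationError(f"{where}: {exc}") from exc


def _build_selectivity(block: dict, where: str) -> SelectivityProfile:
    if not isinstance(block, dict):
        raise InvalidConfigurationError(f"{where}: selectivity must be a mapping")
    try:
        return SelectivityProfile(**block)
    except (TypeError, InvalidConfigurationError) as exc:
        raise InvalidConfigurationError(f"{where}: {exc}") from exc


def _build_specs(blocks: dict) -> dict[str, ProcessSpec]:
    specs: dict[str, ProcessSpec] = {}
    for pid, block in blocks.items():
        if pid not in PROCESS_IDS:
            raise InvalidConfigurationError(
                f"processes.{pid}: unknown process id (expected one of "
                f"{PROCESS_IDS})"
            )
        where = f"processes.{pid}"
        unknown = set(block) - {"schedule", "selectivity", "extras"}
        if unknown:
            raise InvalidConfigurationError(
                f"{where}: unknown keys {sorted(unknown)}"
            )
        schedule = None
        if block.get("schedule") is not None:
            schedule = _build_schedule(block["schedule"], f"{where}.schedule")
        selectivity = None
        if block.get("selectivity") is not None:
            selectivity = _build_selectivity(
                block["selectivity"], f"{where}.selectivity"
            )
        specs[pid] = ProcessSpec(
            pid, schedule, selectivity, dict(block.get("extras", {}))
        )
    return specs


_TOP_KEYS = {
    "n_states",
    "dt",
    "t_end",
    "output_every",
    "equilibrium_tolerance",
    "damage_mode",
    "seed",
    "initial",
    "stop_at_equilibrium",
    "stochastic_window",
    "stochastic_rel_change",
    "record_distributions",
    "processes",
}


def _config_from_dict(data: dict) -> SimulationConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise InvalidConfigurationError(
            f"unknown configuration keys {sorted(unknown)}"
        )
    if "processes" not in data:
        raise InvalidConfigurationError("configuration is missing 'processes'")
    specs = _build_specs(data["processes"])
    kwargs = {k: v for k, v in data.items() if k != "processes"}
    return SimulationConfig(specs=specs, **kwargs)


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML scenario configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidConfigurationError("configuration file must be a mapping")
    return _config_from_dict(data)


def _default_dict() -> dict:
    text = resources.files("mitoqc.data").joinpath("reference.yaml").read_text()
    return yaml.safe_load(text)


def default_config(**overrides) -> SimulationConfig:
    """The reference parameter set, with optional top-level overrides.

    Overrides accept the same keys as the YAML file (``processes`` blocks
    are merged per process, other keys replaced).
    """
    data = _default_dict()
    for key, value in overrides.items():
        if key == "processes":
            for pid, block in value.items():
                merged = copy.deepcopy(data["processes"].get(pid, {}))
                merged.update(block)
                data["processes"][pid] = merged
        else:
            data[key] = value
    return _config_from_dict(data)


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialisable echo of a configuration (for run provenance)."""

    def sched(s):
        if s is None:
            return None
        if isinstance(s, PulseSchedule):
            return {
                "type": "pulse",
                "base_rate": s.base_rate,
                "pulse_rate": s.pulse_rate,
                "pulse_start": s.pulse_start,
                "pulse_end": s.pulse_end,
            }
        return {
            "type": "hill",
            "v_init": s.v_init,
            "v_final": s.v_final,
            "hill_exponent": s.hill_exponent,
            "half_time": s.half_time,
        }

    def sel(s):
        if s is None:
            return None
        return {
            "s_low": s.s_low,
            "s_high": s.s_high,
            "hill_coefficient": s.hill_coefficient,
            "hill_exponent": s.hill_exponent,
            "zero_at_floor": s.zero_at_floor,
        }

    return {
        "n_states": config.n_states,
        "dt": config.dt,
        "t_end": config.t_end,
        "output_every": config.output_every,
        "equilibrium_tolerance": config.equilibrium_tolerance,
        "damage_mode": config.damage_mode,
        "seed": config.seed,
        "stop_at_equilibrium": config.stop_at_equilibrium,
        "processes": {
            pid: {
                "schedule": sched(spec.schedule),
                "selectivity": sel(spec.selectivity),
                "extras": dict(spec.extras),
            }
            for pid, spec in config.specs.items()
        },
    }
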