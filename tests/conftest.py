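"""Shared fixtures: small, fast model configurations for unit tests.

Unit tests run on small quality ladders with accelerated rates so that
equilibration takes seconds; the acceptance tests exercise the full-size
default configuration.
"""

import numpy as np
import pytest

from mitoqc.config import default_config


def fast_processes(n_states: int, ff=0.5, decay=0.01, mitophagy=0.01,
                   rd=0.5, r_max=0.05, id_rate=0.05, eps_max=1):
    """Process blocks with mid-ladder selectivity and accelerated rates."""
    K = (n_states - 1) / 2
    up = {"s_low": 0.0, "s_high": 1.0, "hill_coefficient": K,
          "hill_exponent": 2, "zero_at_floor": True}
    down = {"s_low": 1.0, "s_high": 0.2, "hill_coefficient": K,
            "hill_exponent": 2, "zero_at_floor": False}

    def const(v):
        return {"type": "hill", "v_init": v, "v_final": v,
                "hill_exponent": 0, "half_time": 1.0}

    return {
        "fusion_fission": {"schedule": const(ff), "selectivity": up},
        "decay": {"schedule": const(decay), "selectivity": down},
        "mitophagy": {"schedule": const(mitophagy), "selectivity": down},
        "renewal": {"selectivity": up},
        "random_damage": {"schedule": const(rd), "extras": {"r_max": r_max}},
        "infectious_damage": {
            "schedule": const(id_rate),
            "extras": {"rd_limit": rd / 2, "id_max": id_rate, "eps_max": eps_max},
        },
    }


@pytest.fixture
def fast_config():
    """Factory for small accelerated configurations."""

    def make(n_states=5, mode="none", seed=0, t_end=500.0, dt=0.05,
             output_every=5.0, **kwargs):
        return default_config(
            n_states=n_states,
            dt=dt,
            t_end=t_end,
            output_every=output_every,
            damage_mode=mode,
            seed=seed,
            processes=fast_processes(n_states),
            **kwargs,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
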