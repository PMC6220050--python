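"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from chopnet.anfibers import ANFiberParams
from chopnet.network import (
    EngineConfig,
    attach_step_drive,
    attach_tone_drive,
    build_interval_bank,
    build_pacemaker,
    simulate,
)
from chopnet.stimulus import ToneBurstSpec, make_tone_burst

BANK_REFRACTORIES = [0.5, 0.9, 1.3, 1.7, 2.1]


@pytest.fixture(scope="session")
def pacemaker2_result():
    """Two-neuron pacemaker, step drive + onset, jitter 0, 50 ms."""
    spec = build_pacemaker(n_fast=2)
    attach_step_drive(spec, t_on=0.0, t_off=50.0)
    return spec, simulate(spec, EngineConfig(duration=50.0))


@pytest.fixture(scope="session")
def bank_result():
    """Interval bank on the 0.4 ms pacemaker, jitter 0, 100 ms."""
    spec = build_pacemaker(n_fast=2)
    attach_step_drive(spec, t_on=0.0, t_off=100.0)
    spec = build_interval_bank(BANK_REFRACTORIES, spec)
    return spec, simulate(spec, EngineConfig(duration=100.0))


@pytest.fixture(scope="session")
def fig5_result():
    """Jittered tone-burst protocol: 500 trials, 25 ms burst at 2.89 kHz,
    1.6 ms ramps, synaptic delay jitter SD 0.26 ms."""
    tone = make_tone_burst(ToneBurstSpec(frequency=2890.0, duration=25.0, rise_fall=1.6))
    spec = build_pacemaker(jitter_sd=0.26)
    attach_tone_drive(spec, tone, ANFiberParams())
    return spec, simulate(spec, EngineConfig(duration=35.0, n_trials=500, master_seed=1))
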