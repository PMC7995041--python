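"""Shared fixtures: heavy simulations run once per session."""

import numpy as np
import pytest

from fluidvent import (
    SimulationConfig,
    compute_metrics,
    ec_sweep,
    lung_preset,
    segment_breaths,
    simulate,
)


@pytest.fixture(scope="session")
def healthy_config() -> SimulationConfig:
    """Default calibrated config with the healthy lung preset, 60 s."""
    return SimulationConfig(lung=lung_preset("healthy"))


@pytest.fixture(scope="session")
def default_record(healthy_config):
    return simulate(healthy_config)


@pytest.fixture(scope="session")
def default_metrics(healthy_config, default_record):
    return compute_metrics(
        segment_breaths(default_record), discard=healthy_config.transient_discard
    )


@pytest.fixture(scope="session")
def sweep_table(healthy_config):
    """EC-occlusion sweep over 11 evenly spaced settings in [0, 1]."""
    return ec_sweep(healthy_config, np.linspace(0.0, 1.0, 11))
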