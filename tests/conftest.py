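import numpy as np
import pytest

from mpnmethane.synth import DEFAULT_GEOMETRY, SimulationConfig, \
    simulate_incubation
from mpnmethane.tracer import VesselGeometry, excess_13c_series


@pytest.fixture
def geometry():
    """The study vessel: 200 mL water, 50 mL headspace, 5 mL subsample."""
    return DEFAULT_GEOMETRY


@pytest.fixture
def noiseless_linear_series():
    """Zero-noise forward-simulated series at 0.4 nmol L-1 d-1."""
    cfg = SimulationConfig(seed=0, true_rate=0.4, noise_sd_excess=0.0)
    sim = simulate_incubation(cfg)
    return excess_13c_series(sim.record), sim
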