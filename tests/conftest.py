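import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hicr.datatypes import (
    BackgroundEstimates,
    CalibrationCurve,
    FluorescenceTrace,
    HeatPulseProtocol,
)
from hicr.simulate import SimConfig, mutant_preset


@pytest.fixture
def protocol():
    return HeatPulseProtocol(t_start=10.0, duration=2.0, laser_power_mw=25.6,
                             t0_c=36.0)


@pytest.fixture
def bg_zero():
    return BackgroundEstimates(i_back=0.0, i_laser=0.0)


@pytest.fixture
def calibration():
    return CalibrationCurve()


def make_trace(intensity, dt=0.2, cell_id="c0", channel="fluo4",
               protocol=None, distance_um=20.0):
    """Trace on a regular grid with laser flags from the protocol."""
    intensity = np.asarray(intensity, dtype=float)
    t = np.arange(intensity.size) * dt
    laser = None
    if protocol is not None:
        laser = (t >= protocol.t_start) & (t < protocol.t_end)
    return FluorescenceTrace(cell_id, channel, t, intensity,
                             distance_um=distance_um, laser_on=laser)


def noise_free_config(**overrides) -> SimConfig:
    """Deterministic generator settings (no noise, no bleach, no spont)."""
    from dataclasses import replace

    mut = replace(mutant_preset("WT", 36.0), spont_rate_per_s=0.0)
    defaults = dict(seed=0, n_cells=5, n_unheated=0, noise_sd=0.0,
                    bleach_rate_per_s=0.0, f_baseline_sd=0.0, mutant=mut)
    defaults.update(overrides)
    return SimConfig(**defaults)
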