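import numpy as np
import pytest

from perfquant.image_io_roi import TimeIntensityCurve
from perfquant.synthetic_data import (
    AcquisitionConfig,
    BolusParams,
    ROIPerfusionSpec,
    default_experiment_config,
    gamma_variate,
    simulate_experiment,
)


@pytest.fixture
def acq_noiseless():
    return AcquisitionConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def d3_spec():
    return ROIPerfusionSpec(roi_name="D3", relative_flow=1.0, arrival_delay=0.0,
                            pooling_offset=0.0)


@pytest.fixture
def clean_gamma_curve(acq_noiseless):
    """Unquantized float gamma-variate curve: A=100, baseline=10, alpha=3,
    t_p=6 s, onset 14 s, injection 10 s, 25 fps."""
    t = acq_noiseless.time_grid
    y = gamma_variate(t, BolusParams(onset_time=14.0))
    return TimeIntensityCurve(times=t, intensities=y, injection_time=10.0,
                              roi_name="D3", state_label="T0")


@pytest.fixture(scope="session")
def default_experiment():
    return simulate_experiment(default_experiment_config(seed=0))


def random_bolus_curve(rng, duration=60.0, noise_sd=0.0):
    """A random but analyzable bolus curve (helper shared across tests)."""
    injection = 8.0
    onset = injection + rng.uniform(2.0, 6.0)
    p = BolusParams(
        baseline_level=rng.uniform(5.0, 30.0),
        amplitude=rng.uniform(40.0, 120.0),
        onset_time=onset,
        time_to_peak=rng.uniform(3.0, 10.0),
        shape=rng.uniform(1.5, 5.0),
        recirculation_fraction=rng.uniform(0.0, 0.3),
        recirculation_delay=rng.uniform(20.0, 35.0),
    )
    t = np.arange(int(duration * 25)) / 25.0
    y = gamma_variate(t, p)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.size)
    return TimeIntensityCurve(times=t, intensities=y, injection_time=injection), p
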