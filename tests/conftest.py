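import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calpep import (
    AcquisitionParams,
    BandParams,
    TrajectoryConfig,
    make_2d_timedomain,
    make_trajectory,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def detection_axis():
    return np.arange(1500.0, 1700.0, 2.0)


@pytest.fixture
def standard_band():
    """Single band with moderate heterogeneity; equal-width bivariate model."""
    return BandParams(
        center=1600.0,
        sigma_inhom=12.73,
        sigma_hom=12.73,
        tau_corr=1.0,
        tau_ver=0.5,
        anharmonic_shift=60.0,
    )


@pytest.fixture
def t0_spectrum(standard_band, detection_axis):
    from calpep import build_spectrum

    acq = AcquisitionParams(
        waiting_times=(0.0,), noise_rms=0.0, detection_axis=detection_axis
    )
    td = make_2d_timedomain([standard_band], acq)
    return build_spectrum(td, 0.0)


@pytest.fixture
def scheduled_trajectory():
    """Small trajectory covering all five binding-state categories."""
    cfg = TrajectoryConfig(
        n_frames=500,
        state_fractions={
            "1Ca@COO": 0.26,
            "2Ca@COO": 0.26,
            "1Ca@CO": 0.10,
            "1Ca@COO+1Ca@CO": 0.13,
        },
        seed=11,
    )
    return make_trajectory(cfg)
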