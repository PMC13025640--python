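import numpy as np
import pytest

from usradiomics.rf_core import RFFrame
from usradiomics.synth import PhantomSpec, simulate_rf


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Desk-scale homogeneous Rayleigh phantom used across modules."""
    return PhantomSpec(
        depth_extent_cm=1.5,
        lateral_extent_cm=1.0,
        attenuation_slope=0.0,
        focus_depth_cm=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_frame(small_phantom_spec):
    return simulate_rf(small_phantom_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def narrowband_frame(fc_mhz=5.0, fs=56e6, n_ax=1024, n_lines=12):
    """Pure-tone RF frame used for matched-filter and spectrum checks."""
    t = np.arange(n_ax) / fs
    line = np.cos(2 * np.pi * fc_mhz * 1e6 * t)
    return RFFrame(
        samples=np.tile(line[:, None], (1, n_lines)),
        sampling_rate=fs,
        line_pitch=2e-4,
    )
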