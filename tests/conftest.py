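import numpy as np
import pytest

from frontaleeg.io_formats import HC, MDD, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_recording(rng):
    """90 s of three-channel Gaussian noise at 250 Hz, HC-labelled."""
    data = rng.standard_normal((22500, 3)) * 2.0 + 5.0
    return Recording(subject_id="S001", label=HC, fs=250.0, data=data)


@pytest.fixture
def tiny_cohort():
    """Small, strongly separated synthetic cohort (shared across tests)."""
    from frontaleeg.synthetic import simulate_cohort, well_separated_spec

    spec = well_separated_spec(4, 4, seed=99, duration_s=40.0)
    recordings, manifest = simulate_cohort(spec)
    return recordings, manifest
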