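import numpy as np
import pytest

from bbbdce import AcquisitionParams, AifParams, generate_subject, protocol_aif
from bbbdce.synthetic import default_phantom, uniform_phantom


@pytest.fixture(scope="session")
def acq_short() -> AcquisitionParams:
    """Protocol timing with a shortened dynamic series for fast tests."""
    return AcquisitionParams(n_volumes=120)


@pytest.fixture(scope="session")
def aif_params() -> AifParams:
    return AifParams()


@pytest.fixture(scope="session")
def aif_short(acq_short, aif_params):
    return protocol_aif(acq_short, aif_params)


@pytest.fixture(scope="session")
def noiseless_subject(acq_short, aif_params):
    """Uniform-kinetics subject with zero noise and zero drift."""
    phantom = uniform_phantom(noise_sigma=0.0, drift_slope=0.0)
    return generate_subject(
        phantom, acq_short, aif_params, {1: 1.5e-3}, 0.02, seed=7
    )


@pytest.fixture(scope="session")
def multi_roi_subject(acq_short, aif_params):
    """Default ten-ROI phantom, noiseless, with within-ROI K-trans spread."""
    phantom = default_phantom(noise_sigma=0.0, drift_slope=0.0)
    truth = {rid: 1.0e-3 + 0.1e-3 * rid for rid in range(1, 11)}
    return generate_subject(phantom, acq_short, aif_params, truth, 0.02, seed=21)
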