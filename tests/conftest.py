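import numpy as np
import pytest

from qconv.stimuli import PatchConfig
from qconv.synthetic import generate_stimulus, qc_ground_truth


@pytest.fixture(scope="session")
def small_movie():
    """Short pink-noise movie for geometry and forward-pass tests."""
    return generate_stimulus("pink", 60, 12, 12, seed=7)


@pytest.fixture(scope="session")
def cross_orientation_neuron():
    """Cross-orientation-suppression QC neuron with exact parameters.

    One excitatory quadrature pair at 0 degrees, one suppressive pair at
    90 degrees, uniform 2x2 pooling, calibrated on a pink-noise probe.
    """
    cfg = PatchConfig(10, 10, stride=4, n_lags=1)
    probe = generate_stimulus("pink", 8000, 14, 14, seed=41)
    return qc_ground_truth(
        frame_shape=(14, 14),
        cfg=cfg,
        exc_thetas=(0.0,),
        sup_thetas=(np.pi / 2,),
        movie=probe,
        rule="qc",
    )
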