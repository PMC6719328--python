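import numpy as np
import pytest

from verdict_mri.cohort import PhantomSpec, make_subject
from verdict_mri.dictionary import build_dictionary
from verdict_mri.protocol import five_shell_protocol


@pytest.fixture(scope="session")
def protocol():
    return five_shell_protocol()


@pytest.fixture(scope="session")
def dictionary(protocol):
    return build_dictionary(protocol)


@pytest.fixture(scope="session")
def lgg_subject(protocol):
    """One seeded LGG subject at SNR 50 on a small grid."""
    return make_subject("LGG", 0, PhantomSpec(snr=50.0, shape=(24, 24, 12)), protocol, seed=424242)


def noiseless_measurements(protocol, params):
    """Forward-model measurement vector (b0 rows = 1) for TissueParams."""
    from verdict_mri.models import voxel_signal

    return np.array(
        [1.0 if is_b0 else voxel_signal(params, protocol.shells[i])
         for i, is_b0 in protocol.measurement_layout()]
    )
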