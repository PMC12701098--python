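import numpy as np
import pytest

from ailabel3d import phantom
from ailabel3d.io_prep import VolumePair, znormalize


@pytest.fixture(scope="session")
def small_phantom():
    """One 32x32x12 phantom case with default tissues."""
    return phantom.make_phantom(shape=(32, 32, 12), rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Three 32x32x12 phantom cases."""
    return phantom.make_cohort(3, shape=(32, 32, 12), rng_seed=11)


def normalized_pair(case) -> VolumePair:
    """z-normalized VolumePair of a phantom case, as the networks expect."""
    return VolumePair(
        t1=znormalize(case.pair.t1),
        t2=znormalize(case.pair.t2),
        spacing=case.pair.spacing,
        case_id=case.pair.case_id,
        patient_id=case.pair.patient_id,
    )


def rng(seed=0):
    return np.random.default_rng(seed)
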