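import numpy as np
import pytest

from dwssfp import (
    SequenceParams,
    TissueParams,
    default_sequences,
    make_tensor_phantom,
    protocol_directions,
    simulate_acquisition,
)

# Protocol-like settings shared across the suite: fixed post-mortem tissue
# (T1 = 500 ms, T2 = 30 ms), TR = 30 ms, q = 300 cm^-1 from 52 mT/m x 13.56 ms.


@pytest.fixture(scope="session")
def tissue():
    return TissueParams(T1=500.0, T2=30.0)


@pytest.fixture(scope="session")
def seq():
    return SequenceParams(TR=30.0, alpha_nominal=24.0, delta=13.56, G=52.0)


@pytest.fixture(scope="session")
def sequences():
    return default_sequences()


@pytest.fixture(scope="session")
def small_dirs():
    # 20 DW directions + 3 spoiled non-DW volumes per flip
    return protocol_directions(n_dw=20, n_nondw=3, seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    return make_tensor_phantom((12, 12, 12))


@pytest.fixture(scope="session")
def small_noiseless(small_phantom, small_dirs, sequences):
    return simulate_acquisition(
        small_phantom, small_dirs, sequences, noise_sigma=0.0, seed=5
    )


@pytest.fixture(scope="session")
def small_maps(small_phantom):
    p = small_phantom
    return dict(T1=p.T1, T2=p.T2, B1=p.B1, mask=p.mask, Snf=0.0)


def subsample(mask, every, limit=None):
    """Deterministic voxel subsample of a boolean mask."""
    idx = np.array(np.nonzero(mask)).T[::every]
    if limit:
        idx = idx[:limit]
    out = np.zeros(mask.shape, bool)
    out[tuple(idx.T)] = True
    return out
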