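import numpy as np
import pytest

from ntanet import presets as P
from ntanet.params import StimulusProtocol


@pytest.fixture(scope="session")
def weights():
    return P.single_ensemble_weights()


@pytest.fixture(scope="session")
def rate_params():
    return P.single_ensemble_rate_params()


@pytest.fixture(scope="session")
def gain():
    return P.default_gain()


@pytest.fixture(scope="session")
def std():
    return P.default_std()


@pytest.fixture(scope="session")
def stf():
    return P.default_stf()


@pytest.fixture()
def canonical_protocol():
    """2 s baseline, then gE raised 1.55 -> 3.0 during 2-4 s."""
    return StimulusProtocol.step(
        P.STIM_START, P.STIM_END, dg_e=P.SINGLE_ENSEMBLE_G_STIM - 1.55
    )


def window_mean(traj, attr, t0, t1):
    sel = (traj.t >= t0) & (traj.t < t1)
    return getattr(traj, attr)[sel].mean()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
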