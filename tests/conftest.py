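import numpy as np
import pytest

from permeoskin import BilayerGeometry, Constants, Profile


@pytest.fixture
def constants():
    return Constants()


@pytest.fixture
def geometry():
    return BilayerGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(z, values, kind="pmf", **meta):
    return Profile(z=np.asarray(z, float), values=np.asarray(values, float),
                   kind=kind, metadata={"steps": [], **meta})


@pytest.fixture
def flat_pmf():
    """Zero free energy on a 0.01 nm grid over [0, 5] nm (cell-centered)."""
    z = 0.005 + 0.01 * np.arange(500)
    return make_profile(z, np.zeros_like(z), "pmf")


@pytest.fixture
def unit_diffusion(flat_pmf):
    """D = 1 nm^2/ps on the same grid."""
    return make_profile(flat_pmf.z, np.ones_like(flat_pmf.z), "diffusion")
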