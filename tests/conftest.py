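import numpy as np
import pytest

from seegquake.io import Volume
from seegquake.synth import ElectrodeSpec, make_volume


def gaussian_blob_volume(center, shape=(32, 32, 32), fwhm=2.0, peak=1000.0,
                         background=0.0, affine=None):
    """A single isotropic Gaussian blob at `center` (mm) over a flat background."""
    if affine is None:
        affine = np.eye(4)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    idx = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                               indexing="ij"), -1)
    mm = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    d2 = ((mm - np.asarray(center, dtype=float)) ** 2).sum(-1)
    data = background + peak * np.exp(-d2 / (2 * sigma ** 2))
    return Volume(data=data, affine=np.asarray(affine, dtype=float))


@pytest.fixture(scope="session")
def small_volume():
    """Two straight electrodes in a modest grid; shared across unit tests."""
    spec = ElectrodeSpec(n_electrodes=2, contacts_min=8, contacts_max=10)
    vol, truth = make_volume(spec, shape=(110, 110, 110), seed=7)
    return vol, truth


@pytest.fixture(scope="session")
def noiseless_volume():
    spec = ElectrodeSpec(n_electrodes=2, contacts_min=8, contacts_max=10, noise_sd=0.0)
    vol, truth = make_volume(spec, shape=(110, 110, 110), seed=7)
    return vol, truth
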