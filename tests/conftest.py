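import numpy as np
import pytest

from gstract.phantom import PhantomSpec, make_phantom
from gstract.tensor_field import TensorField


def make_prolate6(direction, lambdas=(1.7e-3, 3e-4, 3e-4)):
    """Six-component prolate tensor with e1 along ``direction``."""
    t = np.asarray(direction, float)
    t = t / np.linalg.norm(t)
    l1, l2, _ = lambdas
    d = l1 - l2
    return np.array([l2 + d * t[0] ** 2, l2 + d * t[1] ** 2,
                     l2 + d * t[2] ** 2, d * t[0] * t[1], d * t[0] * t[2],
                     d * t[1] * t[2]])


def homogeneous_field(shape=(24, 16, 16), direction=(1, 0, 0),
                      voxel_size=2.0, lambdas=(1.7e-3, 3e-4, 3e-4)):
    t6 = make_prolate6(direction, lambdas)
    data = np.broadcast_to(t6, shape + (6,)).copy()
    return TensorField(data, voxel_size=(voxel_size,) * 3)


def isotropic_field(shape=(12, 12, 12), diffusivity=7e-4, voxel_size=2.0):
    data = np.zeros(shape + (6,))
    data[..., :3] = diffusivity
    return TensorField(data, voxel_size=(voxel_size,) * 3)


class PhantomCache:
    """Session-wide memoized phantom datasets with fitted fields.

    Building a 64^3 phantom and fitting its tensors costs several seconds;
    acceptance tests share datasets through this cache.
    """

    def __init__(self):
        self._store = {}

    def get(self, kind, snr, seed=1, **spec_kwargs):
        key = (kind, snr, seed, tuple(sorted(spec_kwargs.items())))
        if key not in self._store:
            ds = make_phantom(PhantomSpec(kind=kind, snr=snr, seed=seed,
                                          **spec_kwargs))
            fitted = ds.fitted_field()
            thr = ds.core_mean_fa(fitted) - 0.1
            self._store[key] = (ds, fitted, thr)
        return self._store[key]


@pytest.fixture(scope="session")
def phantoms():
    return PhantomCache()
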