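import numpy as np
import pytest

from tbseg.phantom import PhantomConfig, generate_phantom
from tbseg.volgrid import LabelMap, Volume


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom (noise 30 HU) with its labels; session-cached."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def clean_phantom_pair():
    """Noise-free phantom for exact-construction oracles."""
    return generate_phantom(PhantomConfig(seed=7, noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(values, spacing=(1.0, 1.0, 1.0), **kw):
    return Volume(values=np.asarray(values, dtype=np.float32), spacing=spacing, **kw)


def make_label(mask, spacing=(1.0, 1.0, 1.0), **kw):
    return LabelMap(mask=np.asarray(mask, dtype=np.uint8), spacing=spacing, **kw)


@pytest.fixture
def random_mask_pairs(rng):
    """Blobby random mask pairs (small, <=500 boundary voxels) for oracles."""

    def _make(n_pairs=10, shape=(9, 9, 9)):
        out = []
        for _ in range(n_pairs):
            a = rng.random(shape) < 0.25
            b = rng.random(shape) < 0.25
            if not a.any():
                a[tuple(rng.integers(0, s) for s in shape)] = True
            if not b.any():
                b[tuple(rng.integers(0, s) for s in shape)] = True
            out.append((a, b))
        return out

    return _make
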