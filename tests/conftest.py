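import numpy as np
import pytest

from gtvseg.image import Mask, Modality, Volume
from gtvseg.phantom import PhantomSpec, TumorSpec, generate_phantom, random_rigid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    return Mask(data=(rng.random(shape) < p).astype(np.uint8), spacing=spacing)


def random_volume(rng, shape=(6, 7, 8), modality=Modality.OTHER):
    spacing = tuple(rng.uniform(0.5, 3.0, 3))
    origin = tuple(rng.uniform(-100, 100, 3))
    return Volume(data=rng.normal(size=shape), spacing=spacing, origin=origin, modality=modality)


def random_rotation(rng):
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def misaligned_phantom():
    """One deterministic phantom with a known rigid PET-frame misalignment."""
    rng = np.random.default_rng(5)
    spec = PhantomSpec(
        misalignment=random_rigid(rng, max_rotation_deg=5.0, max_translation_mm=8.0,
                                  center_mm=(80.0, 80.0, 80.0)),
        seed=7,
    )
    return generate_phantom(spec, case_id="c0")


@pytest.fixture(scope="session")
def aligned_phantom():
    return generate_phantom(PhantomSpec(seed=3), case_id="aligned")
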