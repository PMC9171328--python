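import numpy as np
import pytest

from densefuse.core_io import AtlasLibrary, ImageVolume, LabelVolume
from densefuse.fusion import FusionParams
from densefuse.pipeline import segment_volume
from densefuse.synthdata import PhantomSpec, make_library, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 32-cube phantom with lesions and noise (deterministic)."""
    spec = PhantomSpec(shape=(32, 32, 32), seed=3)
    img, lab, scheme = make_phantom(spec)
    return img, lab, scheme, spec


@pytest.fixture(scope="session")
def tiny_random_case():
    """An 8-cube random-intensity two-member library for oracle checks."""
    rng = np.random.default_rng(0)
    shape = (8, 8, 8)
    affine = np.eye(4)
    subject = ImageVolume(rng.normal(0.0, 1.0, shape), affine)
    members = [
        (
            ImageVolume(rng.normal(0.0, 1.0, shape), affine),
            LabelVolume(rng.integers(0, 3, shape).astype(np.int32), affine),
        )
        for _ in range(2)
    ]
    mask = np.zeros(shape, dtype=bool)
    mask[2:6, 2:6, 2:6] = True
    return subject, AtlasLibrary(members=members), mask


@pytest.fixture(scope="session")
def phantom_library():
    """48-cube, 10-member deformed noisy library (the benchmark conditions)."""
    spec = PhantomSpec(shape=(48, 48, 48), seed=3)
    library, scheme = make_library(spec, 10, seed=11)
    return library, scheme, spec


@pytest.fixture(scope="session")
def loo_segmentation(phantom_library):
    """Leave-one-out pipeline run: member 0 segmented by members 1..9."""
    library, scheme, _ = phantom_library
    subject_img, subject_truth = library.members[0]
    rest = AtlasLibrary(members=library.members[1:])
    result = segment_volume(subject_img, rest, scheme, params=FusionParams(seed=7))
    return result, subject_img, subject_truth, rest, scheme
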