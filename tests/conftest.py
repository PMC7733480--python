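import dataclasses

import numpy as np
import pytest

from aneuseg.phantom import AneurysmSpec, example_spec, generate_phantom, _sample_attachment
from aneuseg.volume import Volume3D


@pytest.fixture(scope="session")
def phantom_case():
    """A small default phantom: skull, three vessels, one ~150 mm³ aneurysm."""
    spec = example_spec(grid_shape=(48, 48, 40), spacing_mm=(0.75, 0.75, 1.0), seed=5)
    rng = np.random.default_rng(2)
    attach, _ = _sample_attachment(spec, rng)
    spec = dataclasses.replace(
        spec, aneurysms=[AneurysmSpec(attach_mm=attach, volume_mm3=150.0)]
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def easy_phantom_case():
    """A phantom with one large, high-contrast aneurysm for learnability tests."""
    spec = example_spec(
        grid_shape=(48, 48, 40), spacing_mm=(0.75, 0.75, 1.0), noise_sd=3.0, seed=5
    )
    rng = np.random.default_rng(2)
    attach, _ = _sample_attachment(spec, rng)
    spec = dataclasses.replace(
        spec, aneurysms=[AneurysmSpec(attach_mm=attach, volume_mm3=400.0)]
    )
    return generate_phantom(spec)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    return Volume3D(arr, spacing)
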