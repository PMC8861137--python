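import dataclasses

import numpy as np
import pytest

from ctoam.phantoms import PhantomSpec, make_phantom
from ctoam.volume_io import Densitogram, PlateMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def noiseless_spec():
    return dataclasses.replace(PhantomSpec(), noise_sd_hu=0.0, trabecular_hu_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    """Phantom without noise, with analytic truth: the reference object
    for end-to-end recovery tests."""
    return make_phantom(noiseless_spec, seed=101)


def random_densitogram(rng, ny, nx, spacing=(0.7, 0.9), hole_p=0.2):
    """Random valid densitogram with holes (helper, not a fixture)."""
    values = rng.uniform(200.0, 2500.0, (ny, nx))
    valid = (rng.random((ny, nx)) > hole_p).astype(np.uint8)
    valid[ny // 2, nx // 2] = 1  # never fully empty
    return Densitogram(
        values=np.where(valid == 1, values, np.nan),
        valid=valid,
        pixel_spacing=spacing,
        meta=PlateMeta(subject="t", level="L4", side="superior", condition="healthy"),
    )
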