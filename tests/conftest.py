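import numpy as np
import pytest

from petrad import (
    CohortSpec,
    PhantomSpec,
    PETVolume,
    make_cohort,
    make_phantom,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Hard-edged uniform sphere: SUV 10 on background 1, no texture/noise."""
    spec = PhantomSpec(
        tumor_suv_max=10.0, texture_amplitude=0.0, noise_sd=0.0, seed=0
    )
    vol, truth = make_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def textured_phantom():
    spec = PhantomSpec(seed=11)
    vol, truth = make_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = make_cohort(CohortSpec(n_patients=120, seed=5))
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_quantised(rng, G=4, shape=(6, 6, 6), p_mask=0.7):
    """A random labelled VOI for oracle comparisons."""
    from petrad.texture import QuantisedVOI

    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    labels = np.where(mask, rng.integers(1, G + 1, shape), 0).astype(np.int32)
    return QuantisedVOI(labels, mask, G, 0.0, 1.0)
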