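import numpy as np
import pytest

from mritool import MapConfig, SpeckleParams, apply_speckle, denoise_image, make_phantom

# Standard fixture suite: three phantom kinds at two speckle levels, the
# conditions under which denoising quality is evaluated throughout.
SUITE_CASES = [
    (kind, phantom_seed, d)
    for d in (0.3, 0.5)
    for kind, phantom_seed in (("blobs", 1), ("shepp_like", 2), ("step_wedge", 3))
]
ADDITIVE_SIGMA = 1e-3


def build_case(kind, phantom_seed, d, shape=(64, 64)):
    clean = make_phantom(shape, kind, phantom_seed)
    noisy = apply_speckle(
        clean, SpeckleParams(d=d, additive_sigma=ADDITIVE_SIGMA, seed=50 + phantom_seed)
    )
    return clean, noisy


@pytest.fixture(scope="session")
def fixture_suite():
    """(kind, d, clean, noisy) for each of the six standard cases."""
    return [(kind, d, *build_case(kind, seed, d)) for kind, seed, d in SUITE_CASES]


@pytest.fixture(scope="session")
def denoised_suite(fixture_suite):
    """The standard suite plus the denoise report for each case."""
    return [
        (kind, d, clean, noisy, denoise_image(noisy, MapConfig(speckle_scale=d)))
        for kind, d, clean, noisy in fixture_suite
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
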