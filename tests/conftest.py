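import numpy as np
import pytest

from pgpem import (
    ForwardModelParams,
    RestoreConfig,
    estimate_noise,
    make_phantom,
    make_psf_inverse_square,
    run_pgpem,
    scale_to_peak_counts,
    simulate_dar,
)


@pytest.fixture(scope="session")
def point_fixture():
    """Point-source phantom blurred at gap 4 with moderate noise: the
    standard resolution fixture."""
    psf = make_psf_inverse_square(4)
    phantom = scale_to_peak_counts(make_phantom("points", (128, 128), seed=3), psf, 50)
    raw = simulate_dar(phantom, psf, ForwardModelParams(alpha=1, b=10, sigma_g=2, seed=3))
    return phantom, psf, raw


@pytest.fixture(scope="session")
def point_noise(point_fixture):
    _, _, raw = point_fixture
    return estimate_noise(raw)


@pytest.fixture(scope="session")
def point_restored(point_fixture, point_noise):
    _, _, raw = point_fixture
    return run_pgpem(raw, point_noise, RestoreConfig())


@pytest.fixture(scope="session")
def bone_fixture():
    """Bone-section phantom with ring-concentrated activity, narrow blur."""
    psf = make_psf_inverse_square(2)
    phantom = scale_to_peak_counts(make_phantom("bone_section", (128, 128), seed=7), psf, 200)
    raw = simulate_dar(phantom, psf, ForwardModelParams(alpha=1, b=10, sigma_g=2, seed=7))
    return phantom, psf, raw


@pytest.fixture(scope="session")
def bone_restored(bone_fixture):
    _, _, raw = bone_fixture
    noise = estimate_noise(raw)
    return run_pgpem(raw, noise, RestoreConfig())
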