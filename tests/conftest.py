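import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from organoidphasor import (
    decay_to_phasor,
    make_organoid_phantom,
    make_reference_decay,
    simulate_decay_cube,
)

OMEGA = 2.0 * np.pi / 12.5


@pytest.fixture(scope="session")
def phantom():
    """Small two-layer organoid phantom: glycolytic rim, oxidative core."""
    return make_organoid_phantom(
        height=64,
        width=64,
        outer_radius=24,
        rim_thickness=6,
        rim_free_fraction=0.7,
        core_free_fraction=0.3,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_cube(phantom):
    return simulate_decay_cube(phantom, noise="none", n_bins=256, seed=1)


@pytest.fixture(scope="session")
def reference_cube():
    return make_reference_decay(tau_ref=2.5, n_bins=256, frame_shape=(8, 8))


@pytest.fixture(scope="session")
def reference_field(reference_cube):
    return decay_to_phasor(reference_cube)


def mono_exp_cube(tau, n_bins=256, rep_period=12.5, shape=(4, 4), photons=1e4):
    """Uniform noiseless mono-exponential cube (helper, not a fixture)."""
    phantom = make_reference_decay(
        tau_ref=tau,
        n_bins=n_bins,
        rep_period=rep_period,
        frame_shape=shape,
        photons_per_pixel=photons,
    )
    return phantom
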