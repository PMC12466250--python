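import numpy as np
import pytest

from cineclust.phantom import LesionSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def lesion_phantom():
    """A 128x128, 20-frame cycle with one akinetic bright lesion."""
    cfg = PhantomConfig(
        height=128, width=128, n_frames=20, ring_radii=(26.0, 40.0),
        contraction_amplitude=0.1,
        lesion_specs=(LesionSpec(center=(40.0, 64.0), radius=9.0,
                                 intensity_delta=0.2, motion_damping=0.8),),
        noise_sd=0.01, seed=7)
    seq, truth = generate_phantom(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """A small noise-free phantom without lesions."""
    cfg = PhantomConfig(height=96, width=96, n_frames=10, ring_radii=(20.0, 30.0),
                        contraction_amplitude=0.1, noise_sd=0.0, seed=3)
    seq, truth = generate_phantom(cfg)
    return cfg, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
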