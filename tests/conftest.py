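import numpy as np
import pytest

import calcistream as cs


@pytest.fixture(scope="session")
def small_protocol():
    """Six odours, 30-frame windows, 5 Hz — a 190-frame recording."""
    return cs.generate_protocol(
        [f"o{i}" for i in range(6)], interstimulus_frames=30,
        lead_in_frames=10, frame_rate=5.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_truth(small_protocol):
    """Noiseless 4-unit ground truth: exact mixture, no nuisance terms."""
    return cs.generate_ground_truth(
        image_shape=(48, 48), n_units=4, radius_range=(3.0, 5.0),
        protocol=small_protocol, noise_sigma=0.0, n_background=0,
        spontaneous_amplitude=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def small_movie(small_truth):
    return cs.render_movie(small_truth)


@pytest.fixture(scope="session")
def noisy_truth():
    """Small noisy movie with background structure, SNR 5."""
    protocol = cs.generate_protocol(
        [f"o{i}" for i in range(8)], interstimulus_frames=40,
        lead_in_frames=20, frame_rate=5.0, seed=5, total_frames=800,
    )
    return cs.generate_ground_truth(
        image_shape=(60, 80), n_units=8, radius_range=(3.0, 5.0),
        protocol=protocol, noise_sigma=0.2, n_background=4, seed=5,
    )


@pytest.fixture(scope="session")
def noisy_movie(noisy_truth):
    return cs.render_movie(noisy_truth, dtype=np.float32)
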