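import numpy as np
import pytest

from dsaflow import DSASequence, PhantomConfig, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sequence():
    """Tiny deterministic ramp sequence with metadata, no phantom physics."""
    frames = np.stack([np.full((8, 10), float(k)) for k in range(6)])
    frames[:, 2:5, 3:7] += 1.5
    return DSASequence(frames, frame_rate=10.0, pixel_spacing=0.4,
                       phase_labels=["baseline", "baseline", "filling",
                                     "filling", "filling", "collateral"])


def make_phantom(**overrides):
    """Phantom factory with small, fast defaults shared across tests."""
    params = dict(image_shape=(96, 128), n_frames=40, frame_rate=15.0,
                  pixel_spacing=0.5, vessel_width=10.0, thrombus_length=1.6,
                  bolus_transit_delay_true=0.3, n_baseline_frames=4,
                  collateral_fraction=0.0, seed=7)
    params.update(overrides)
    return generate_sequence(PhantomConfig(**params))


@pytest.fixture
def phantom_factory():
    return make_phantom
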