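import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sonoderm import PhantomSpec, UltrasoundFrame, generate_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def noise_free_spec():
    """Phantom with every noise source disabled: constant-intensity bands."""
    return PhantomSpec(
        roughness_amplitude_px=0.0,
        thickness_jitter_px=0.0,
        speckle_shape=None,
        seed=7,
    )


@pytest.fixture
def noise_free_frame(noise_free_spec):
    return generate_frame(noise_free_spec)


@pytest.fixture
def small_frame():
    """A tiny frame with uniform spacing for geometry unit tests."""
    return UltrasoundFrame(
        np.zeros((64, 120), dtype=np.uint8),
        axial_spacing_mm_per_px=0.02,
        lateral_spacing_mm_per_px=0.05,
        frame_id="unit",
    )


def rect_annotation(layer="entry_echo", upper=10, lower=20, c0=0, c1=100):
    from sonoderm import LayerAnnotation

    return LayerAnnotation(
        layer,
        [(c0, upper), (c1 - 1, upper)],
        [(c0, lower), (c1 - 1, lower)],
        (c0, c1),
    )
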