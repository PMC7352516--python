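import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stainslice import GreyImage

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def worked_3x3() -> GreyImage:
    """3x3 image whose only pixel inside 160-180 is the 170."""
    return GreyImage(np.array([[100, 150, 170], [190, 210, 230], [250, 255, 160]], np.uint8))


@pytest.fixture()
def one_per_level() -> GreyImage:
    """16x16 image holding each grey level 0..255 exactly once."""
    return GreyImage(np.arange(256, dtype=np.uint8).reshape(16, 16))


def make_sierpinski(level: int = 6) -> GreyImage:
    """Sierpinski carpet: set pixels black (0), background white (255)."""
    a = np.array([[1]], dtype=np.uint8)
    for _ in range(level):
        a = np.block([[a, a, a], [a, np.zeros_like(a), a], [a, a, a]])
    return GreyImage(np.where(a == 1, 0, 255).astype(np.uint8))


@pytest.fixture(scope="session")
def sierpinski6() -> GreyImage:
    return make_sierpinski(6)
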