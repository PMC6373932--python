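import numpy as np
import pytest

from leaftooth import PipelineConfig, extract_features, generate_leaf
from leaftooth.synthetic import SyntheticLeafSpec


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    """Boolean disk mask (exact pixel-centre rasterisation)."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_mask(a: int, b: int, pad: int = 4) -> np.ndarray:
    size_y = 2 * (b + pad) + 1
    size_x = 2 * (a + pad) + 1
    cy, cx = b + pad, a + pad
    yy, xx = np.mgrid[:size_y, :size_x]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def simple_leaf():
    """One clean 12-tooth leaf image with its ground truth."""
    spec = SyntheticLeafSpec(
        n_teeth=12, flank_style="st", sinus_style="angular",
        tooth_amplitude=53.0, seed=42,
    )
    img, gt = generate_leaf(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def simple_leaf_record(simple_leaf):
    _, img, _ = simple_leaf
    return extract_features(img, PipelineConfig())
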