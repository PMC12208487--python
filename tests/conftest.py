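import numpy as np
import pytest
from hypothesis import strategies as st

from usaug.phantom_synth import PhantomConfig, generate_phantom, write_phantom_dataset
from usaug.yolo_dataset import LabeledBox


@st.composite
def labeled_boxes(draw, class_count=6, with_confidence=False):
    """Strategy for valid in-image boxes."""
    w = draw(st.floats(0.02, 1.0))
    h = draw(st.floats(0.02, 1.0))
    cx = draw(st.floats(w / 2, 1 - w / 2)) if w < 1 else 0.5
    cy = draw(st.floats(h / 2, 1 - h / 2)) if h < 1 else 0.5
    conf = draw(st.floats(0.0, 1.0)) if with_confidence else None
    return LabeledBox(
        class_id=draw(st.integers(0, class_count - 1)),
        cx=cx, cy=cy, w=w, h=h, confidence=conf,
    )


def random_box(rng, class_count=6, confidence=False):
    w = rng.uniform(0.05, 0.6)
    h = rng.uniform(0.05, 0.6)
    return LabeledBox(
        class_id=int(rng.integers(class_count)),
        cx=rng.uniform(w / 2, 1 - w / 2),
        cy=rng.uniform(h / 2, 1 - h / 2),
        w=w,
        h=h,
        confidence=float(rng.uniform(0.01, 1.0)) if confidence else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def speckle_image(rng):
    """A 64x64 speckle-like raster."""
    img = rng.gamma(4.0, 30.0, size=(64, 64))
    return np.clip(img, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def big_phantom():
    """~10^4 nodules; shared across statistical tests to keep the suite fast."""
    cfg = PhantomConfig(
        image_size=64, n_images=3400, nodules_per_image=(2, 4), seed=777
    )
    return generate_phantom(cfg)


@pytest.fixture
def small_phantom_manifest(tmp_path):
    cfg = PhantomConfig(image_size=64, n_images=12, nodules_per_image=(1, 2), seed=3)
    records = generate_phantom(cfg)
    return write_phantom_dataset(records, tmp_path / "data")
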