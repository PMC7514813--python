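import numpy as np
import pytest

from csdgait.silhouettes import BinarySilhouette


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frames(masks, start_index=0):
    """Wrap a stack of binary arrays as consecutive silhouette frames."""
    return [
        BinarySilhouette(mask=m, frame_index=start_index + i)
        for i, m in enumerate(masks)
    ]


@pytest.fixture
def random_window():
    """Factory: n random consecutive binary frames of a given size."""

    def _make(n, h=12, w=10, seed=0, density=0.5):
        r = np.random.default_rng(seed)
        return make_frames((r.random((n, h, w)) < density).astype(np.uint8))

    return _make
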