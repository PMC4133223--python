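import numpy as np
import pytest
from scipy import ndimage


def smooth_random_patch(seed: int, size: int = 41, blur: float = 2.0) -> np.ndarray:
    """Band-limited random field in [0, 1] — generic 'textured image' input."""
    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.normal(size=(size, size)), blur, mode="reflect")
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


@pytest.fixture(scope="session")
def smooth_patch() -> np.ndarray:
    return smooth_random_patch(seed=12345)
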