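import numpy as np
import pytest

from heterorad.imaging import ImageVolume, RoiMask, RoiSample, extract_roi


def roi_from_array(arr, mask=None, spacing=(1.0, 1.0, 1.0)) -> RoiSample:
    """Build an RoiSample from a raw HU array (full mask by default)."""
    arr = np.asarray(arr, dtype=float)
    vol = ImageVolume(arr, spacing)
    m = RoiMask(np.ones(arr.shape, bool) if mask is None else np.asarray(mask))
    return extract_roi(vol, m)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
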