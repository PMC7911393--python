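import numpy as np
import pytest

from petmtv import SUVVolume


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    """Wrap an array (padded to 3-D) as an SUVVolume."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 3:
        arr = arr[..., None]
    return SUVVolume(values=arr, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20210126)
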