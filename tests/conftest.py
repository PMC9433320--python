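import numpy as np
import pytest

from mitoquant.imgio import BinaryMask, Calibration


@pytest.fixture
def cal01() -> Calibration:
    """0.1 μm/px, the default scene calibration."""
    return Calibration(pixel_size_xy=0.1)


@pytest.fixture
def disc_mask(cal01) -> BinaryMask:
    """Hard-edged disc of radius 3 μm (30 px) in a 100×100 frame."""
    yy, xx = np.mgrid[0:100, 0:100]
    return BinaryMask((yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2, cal01)
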