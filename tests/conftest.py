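import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from radsurv.preprocess import DiscretizedVoi
from radsurv.volume import ImageVolume, VoiMask


def make_voi(shape=(6, 5, 4), n_levels=4, seed=0, p_mask=0.7, spacing=(1.0, 1.0, 1.0)):
    """Random small discretized VOI for brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    voi = DiscretizedVoi(
        levels, n_levels, VoiMask(mask, spacing), binning={"method": "direct"}
    )
    return voi


def make_volume_pair(values, spacing=(1.0, 1.0, 1.0), mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return ImageVolume(values, spacing), VoiMask(mask, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
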