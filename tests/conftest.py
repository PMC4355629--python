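import numpy as np
import pytest

from synfoci import SynapseParams
from synfoci.simulate import background_profile, cell_mask


@pytest.fixture
def default_params():
    return SynapseParams(seed=1234)


@pytest.fixture
def quiet_params():
    """Noise-free default scene for exact geometric assertions."""
    return SynapseParams(seed=1234, noise=False)


@pytest.fixture
def disk_cell():
    """A bare disk footprint (no objects) with its background profile."""
    p = SynapseParams(seed=0, n_foci=0, n_clusters=0, noise=False)
    return p, background_profile(p), cell_mask(p)


def brute_force_rank_filter(pixels: np.ndarray, percentile: float, w: int) -> np.ndarray:
    """Independent oracle: per-pixel sorted-window nearest-rank percentile
    with symmetric (reflect-including-edge) padding."""
    pad = w // 2
    padded = np.pad(pixels, pad, mode="symmetric")
    out = np.empty_like(pixels, dtype=pixels.dtype)
    n = w * w
    k = int(np.ceil(percentile / 100.0 * n)) - 1
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            window = np.sort(padded[r : r + w, c : c + w], axis=None)
            out[r, c] = window[k]
    return out
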