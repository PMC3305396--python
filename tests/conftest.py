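import logging

import numpy as np
import pytest

from autorif import Calibration, FilterSettings, ImageStack, segment_nuclei
from autorif import synthetic_fixtures as synth

# detection logs expected no-focus / clamp warnings on degenerate fixtures
logging.getLogger("autorif").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_stack():
    """Tiny deterministic 3-slice 8-bit stack."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 256, size=(3, 12, 10), dtype=np.uint16).astype(np.uint8)
    return ImageStack(data.astype(np.uint8), bit_depth=8, channel_tag="focus")


@pytest.fixture(scope="session")
def medium_field():
    """One rendered 10-slice field with four medium-sized foci (session-cached)."""
    truth = synth.default_truth(
        4, seed=11, shape=(10, 256, 256), sigma_choices_xy_px=[synth.SIGMA_MEDIUM_PX]
    )
    nuclear, focus = synth.render_field(truth, (10, 256, 256))
    return truth, nuclear, focus


@pytest.fixture(scope="session")
def medium_field_nucleus(medium_field):
    truth, nuclear, focus = medium_field
    regions = segment_nuclei(nuclear)
    assert len(regions) == 1 and not regions[0].excluded
    return truth, focus, regions[0]


def random_histogram(rng, n_bins=256, max_count=50):
    """A random nonnegative integer histogram with >= 2 occupied bins."""
    while True:
        hist = rng.integers(0, max_count, size=n_bins)
        hist[rng.random(n_bins) < 0.3] = 0
        if np.count_nonzero(hist) >= 2:
            return hist


def random_region(rng, n_min=3, n_max=60, span=30):
    """A random set of distinct (u, v) pixel coordinates as an (N, 2) array."""
    n = int(rng.integers(n_min, n_max + 1))
    seen = set()
    while len(seen) < n:
        seen.add((int(rng.integers(0, span)), int(rng.integers(0, span))))
    return np.array(sorted(seen))
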