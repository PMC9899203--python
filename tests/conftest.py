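import numpy as np
import pytest

from lungphen import make_phantom_volume, segment_lung


@pytest.fixture(scope="session")
def phantom_pair():
    """One phenotype-1 / phenotype-2 phantom pair (medium kernel), shared."""
    return (
        make_phantom_volume(1, "medium", seed=42, scan_id="p1"),
        make_phantom_volume(2, "medium", seed=42, scan_id="p2"),
    )


@pytest.fixture(scope="session")
def segmented_phantom(phantom_pair):
    scan = phantom_pair[0]
    return scan, segment_lung(scan.volume)


@pytest.fixture(scope="session")
def random_windows():
    """100 random 6x6x6 gray-level windows (levels 1..8 with masked voxels)."""
    rng = np.random.default_rng(2024)
    windows = []
    for _ in range(100):
        lv = rng.integers(1, 9, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.85
        lv = np.where(mask, lv, 0)
        windows.append(lv)
    return windows
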