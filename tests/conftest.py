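import numpy as np
import pytest

from biofilmscape import synthetic, texture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20131126)


@pytest.fixture(scope="session")
def image_pair_512():
    """Full-menu-capable synthetic image pair (both dims exceed the 400 px offset)."""
    lp = synthetic.LandscapeParams(dims=(512, 512), complexity=0.6, seed=11)
    return synthetic.generate_landscape_image(lp)


@pytest.fixture
def small_image():
    px = np.array([[10, 200, 10, 200],
                   [50, 50, 120, 120],
                   [10, 200, 10, 200],
                   [255, 0, 255, 0]], dtype=np.uint8)
    return texture.GrayImage(px, "transmitted")


def sgldm_oracle(pixels: np.ndarray, angle_deg: int, d: int) -> np.ndarray:
    """Exhaustive pair-enumeration co-occurrence oracle (loops, no vectorizing)."""
    n_rows, n_cols = pixels.shape
    counts = np.zeros((256, 256))
    for r in range(n_rows):
        for c in range(n_cols):
            if angle_deg == 0:
                r2, c2 = r, c + d
            else:
                r2, c2 = r - d, c + d
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                counts[pixels[r, c], pixels[r2, c2]] += 1
                counts[pixels[r2, c2], pixels[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts
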