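import numpy as np
import pytest

from phylopix.synth import RenderSpec, random_tree, render_tree


@pytest.fixture
def blank():
    """All-background 60x80 raster factory."""

    def make(h: int = 60, w: int = 80) -> np.ndarray:
        return np.zeros((h, w), dtype=bool)

    return make


@pytest.fixture
def five_leaf_truth():
    """Small clean render used by several modules."""
    root = random_tree(5, multifurcation_prob=0.0, seed=11)
    return render_tree(root, RenderSpec())


def brute_force_thickness(mask: np.ndarray, min_run: int = 15) -> float:
    """Independent oracle: median vertical run length over columns interior
    to long horizontal runs, by direct per-pixel scanning."""
    h, w = mask.shape
    samples = []
    seen = set()
    for y in range(h):
        x = 0
        while x < w:
            if not mask[y, x]:
                x += 1
                continue
            x1 = x
            while x1 < w and mask[y, x1]:
                x1 += 1
            if x1 - x >= min_run:
                for col in range(x, x1):
                    top = y
                    while top > 0 and mask[top - 1, col]:
                        top -= 1
                    if (col, top) in seen:
                        continue
                    seen.add((col, top))
                    bot = top
                    while bot + 1 < h and mask[bot + 1, col]:
                        bot += 1
                    samples.append(bot - top + 1)
            x = x1
    assert samples, "oracle found no long horizontal runs"
    return float(np.median(samples))
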