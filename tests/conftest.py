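import numpy as np
import pytest

from qdfish.psf import PSFModel


@pytest.fixture
def psf() -> PSFModel:
    return PSFModel(sigma_px=1.2, window_half=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180)


def greedy_match(truths, records, radius=2.0):
    """One-to-one greedy matching of truth spots to detections.

    Returns the number of matched (true-positive) pairs.  ``truths`` is a
    list of objects with .x/.y, ``records`` with .x_sub/.y_sub.
    """
    used = set()
    tp = 0
    for t in truths:
        best = None
        bd = radius * radius
        for i, r in enumerate(records):
            if i in used:
                continue
            d = (t.x - r.x_sub) ** 2 + (t.y - r.y_sub) ** 2
            if d <= bd:
                bd = d
                best = i
        if best is not None:
            used.add(best)
            tp += 1
    return tp
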