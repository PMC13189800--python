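"""Shared fixtures: analytic masks and small synthetic datasets."""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def disk_mask():
    """Filled digital disk, r=100, in a 300x300 frame."""
    yy, xx = np.mgrid[0:300, 0:300]
    return (xx - 150) ** 2 + (yy - 150) ** 2 <= 100 ** 2


@pytest.fixture(scope="session")
def square_mask():
    """Axis-aligned filled square, side 100."""
    m = np.zeros((200, 200), bool)
    m[50:150, 50:150] = True
    return m


@pytest.fixture(scope="session")
def separable_2class():
    """Two well-separated Gaussian classes: 250 + 250 samples, 4 features."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0.0, 1.0, (250, 4)),
                   rng.normal(2.5, 1.0, (250, 4))])
    y = np.array(["a"] * 250 + ["b"] * 250)
    return X, y


@pytest.fixture(scope="session")
def three_class_redundant():
    """3 informative classes, 5 features, one duplicated column (x4 = x0)."""
    import pandas as pd

    rng = np.random.default_rng(1)
    n = 60
    means = [(0, 0, 0), (2, 0, 1), (0, 2, -1)]
    blocks, labels = [], []
    for k, m in enumerate(means):
        b = rng.normal(0, 1, (n, 3)) + np.asarray(m)
        blocks.append(np.column_stack([b, rng.normal(0, 1, n)]))
        labels += [f"c{k}"] * n
    X = np.vstack(blocks)
    X = np.column_stack([X, X[:, 0]])  # duplicate of x0
    return (pd.DataFrame(X, columns=["x0", "x1", "x2", "noise", "x0_dup"]),
            np.array(labels))
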