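import numpy as np
import pytest

from viscnet import build_fcc


@pytest.fixture(scope="session")
def net_h3():
    return build_fcc(3, ell=1.1, k=100.0)


@pytest.fixture(scope="session")
def net_h4():
    return build_fcc(4, ell=1.1, k=800.0)


@pytest.fixture(scope="session")
def net_h6():
    return build_fcc(6, ell=1.1, k=800.0)


def brute_force_bonds(positions: np.ndarray, ell: float, box) -> set:
    """O(N^2) all-pairs neighbor scan (minimum image in x, y)."""
    Lx, Ly, _ = box
    n = len(positions)
    pairs = set()
    for i in range(n):
        d = positions[i + 1:] - positions[i]
        d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
        d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
        r = np.sqrt((d ** 2).sum(axis=1))
        for off in np.flatnonzero(np.abs(r - ell) < 1e-6 * ell):
            pairs.add((i, i + 1 + int(off)))
    return pairs
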