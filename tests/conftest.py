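"""Shared fixtures and independent oracles used across the test suite."""

import numpy as np
import pytest

from paleorange.io_formats import EnvSlice, RasterGrid


# ---------------------------------------------------------------------------
# Independent brute-force oracles (never share code with the implementation)
# ---------------------------------------------------------------------------

def flood_fill_components(mask: np.ndarray, adjacency: str) -> np.ndarray:
    """Reference connected-component labeling by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if adjacency == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 1
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    ci, cj = stack.pop()
                    for di, dj in offsets:
                        ni, nj = ci + di, cj + dj
                        if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                                and mask[ni, nj] and labels[ni, nj] == 0):
                            labels[ni, nj] = nxt
                            stack.append((ni, nj))
                nxt += 1
    return labels


def brute_force_occupancy(prev_labels, prev_occupied, next_labels, radius):
    """Reference occupancy propagation by all-pairs Chebyshev distances."""
    occ_cells = np.argwhere(np.isin(prev_labels, list(prev_occupied)))
    flags = set()
    for comp in np.unique(next_labels[next_labels > 0]):
        cells = np.argwhere(next_labels == comp)
        done = False
        for ci, cj in cells:
            for oi, oj in occ_cells:
                if max(abs(int(ci) - int(oi)), abs(int(cj) - int(oj))) <= radius:
                    flags.add(int(comp))
                    done = True
                    break
            if done:
                break
    return flags


# ---------------------------------------------------------------------------
# Small shared inputs
# ---------------------------------------------------------------------------

@pytest.fixture
def small_grid() -> RasterGrid:
    vals = np.arange(12, dtype=float).reshape(3, 4)
    return RasterGrid(vals, xll=10.0, yll=0.0, cellsize=0.5)


@pytest.fixture
def two_var_slice() -> EnvSlice:
    rng = np.random.default_rng(77)
    a = RasterGrid(rng.uniform(0, 10, (8, 8)), 0.0, 0.0, 1.0)
    b = RasterGrid(rng.uniform(-5, 5, (8, 8)), 0.0, 0.0, 1.0)
    return EnvSlice(0.0, {"env1": a, "env2": b})
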