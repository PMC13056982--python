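import numpy as np
import pytest

from aevindex.synthetic import ScenarioConfig, antarctic_grid, generate_environment


@pytest.fixture(scope="session")
def grid2deg():
    return antarctic_grid(2.0, 2.0)


@pytest.fixture(scope="session")
def small_env(grid2deg):
    """Two-member, two-year synthetic environment shared across tests."""
    cfg = ScenarioConfig(years=(2000, 2002), n_members=2, seed=42)
    return cfg, generate_environment(grid2deg, cfg)


def bfs_flood_fill(below: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent brute-force polynya labelling oracle.

    Breadth-first flood fill over the below-threshold mask with
    longitude wrap, then discard components touching the top (northern)
    row.  Shares no code with the package implementation.
    """
    nlat, nlon = below.shape
    labels = np.zeros((nlat, nlon), dtype=int)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    current = 0
    for i0 in range(nlat):
        for j0 in range(nlon):
            if below[i0, j0] and labels[i0, j0] == 0:
                current += 1
                queue = [(i0, j0)]
                labels[i0, j0] = current
                while queue:
                    i, j = queue.pop()
                    for di, dj in steps:
                        ii, jj = i + di, (j + dj) % nlon  # wrap in longitude
                        if 0 <= ii < nlat and below[ii, jj] and labels[ii, jj] == 0:
                            labels[ii, jj] = current
                            queue.append((ii, jj))
    open_ids = set(labels[-1, :][labels[-1, :] > 0].tolist())
    for oid in open_ids:
        labels[labels == oid] = 0
    return labels


def label_partition(labels: np.ndarray) -> set[frozenset]:
    """Canonical form of a labelling: the set of component cell-sets."""
    out = set()
    for lab in np.unique(labels):
        if lab > 0:
            out.add(frozenset(map(tuple, np.argwhere(labels == lab))))
    return out
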