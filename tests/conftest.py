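import numpy as np
import pytest

from greenscape.grid import ClassEntry, ClassScheme, GLOBELAND30, LandCoverGrid


@pytest.fixture
def scheme():
    return GLOBELAND30


@pytest.fixture
def two_class_scheme():
    return ClassScheme((ClassEntry(1, "a", True), ClassEntry(2, "b", False)))


@pytest.fixture
def uniform_grid():
    """10x10 all-forest map with 100 m cells."""
    return LandCoverGrid(np.full((10, 10), 20))


@pytest.fixture
def checkerboard(two_class_scheme):
    values = np.indices((8, 8)).sum(axis=0) % 2 + 1
    return LandCoverGrid(values, scheme=two_class_scheme)


def brute_force_patches(values, nodata, connectivity):
    """Independent flood-fill patch labeler (BFS, pure Python)."""
    rows, cols = values.shape
    labels = np.zeros((rows, cols), dtype=int)
    if connectivity == 4:
        moves = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    next_id = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if values[r0, c0] == nodata or labels[r0, c0]:
                continue
            next_id += 1
            cls = values[r0, c0]
            stack = [(r0, c0)]
            labels[r0, c0] = next_id
            while stack:
                r, c = stack.pop()
                for dr, dc in moves:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < rows and 0 <= cc < cols
                            and not labels[rr, cc]
                            and values[rr, cc] == cls):
                        labels[rr, cc] = next_id
                        stack.append((rr, cc))
    return labels, next_id
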