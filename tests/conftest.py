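import numpy as np
import pytest

from nisslsplit.volume import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(arr, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(arr), spacing)


@pytest.fixture
def pompon_volume():
    """Dark core (r=8 µm, gray 60) with pale rim (8–14 µm, gray 180) on 120."""
    arr = np.full((48, 48, 48), 120, dtype=np.uint8)
    zz, yy, xx = np.ogrid[:48, :48, :48]
    d2 = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2
    arr[d2 <= 14**2] = 180
    arr[d2 <= 8**2] = 60
    return Volume(arr, (1.0, 1.0, 1.0))


@pytest.fixture
def dark_ball_volume():
    """Same-size solid dark ball, no pale rim (comparison fixture)."""
    arr = np.full((48, 48, 48), 120, dtype=np.uint8)
    zz, yy, xx = np.ogrid[:48, :48, :48]
    arr[(zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 8**2] = 60
    return Volume(arr, (1.0, 1.0, 1.0))


def digitized_ball(radius_um, spacing=(1.0, 1.0, 1.0), pad=3):
    """Boolean voxelization of a sphere, center on a voxel."""
    spacing = np.asarray(spacing, float)
    r_vox = np.ceil(radius_um / spacing).astype(int) + pad
    shape = 2 * r_vox + 1
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, r_vox, spacing))
    return d2 <= radius_um**2


def flood_fill_oracle(values, threshold, seeds):
    """Brute-force BFS flood fill of {v >= threshold} from seed voxels, 26-conn."""
    from collections import deque

    grow = values >= threshold
    out = np.zeros_like(grow)
    shape = values.shape
    q = deque(map(tuple, np.argwhere(seeds & grow)))
    for t in q:
        out[t] = True
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx_ = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx_ < shape[2]:
                if grow[nz, ny, nx_] and not out[nz, ny, nx_]:
                    out[nz, ny, nx_] = True
                    q.append((nz, ny, nx_))
    return out
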