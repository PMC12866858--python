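import numpy as np
import pytest

from msifuse.phantom import PhantomSpec, generate_phantom
from msifuse.preprocess import validate_registration


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """32x32 truth, magnification 4: fast enough for per-test training."""
    spec = PhantomSpec(hr_shape=(32, 32), magnification=4, n_cells=10,
                       noise_sd=0.02, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_pair(small_phantom):
    return validate_registration(small_phantom.microscopy, small_phantom.ion_lr, 4)


# ---------------------------------------------------------------------------
# Scalar brute-force oracles, shared across modules.  These stay deliberately
# naive (explicit Python loops, index clamping for replicate padding) so they
# are independent of the vectorized implementations they check.
# ---------------------------------------------------------------------------

def oracle_mse(a, b):
    total = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            total += (a[i, j] - b[i, j]) ** 2
    return total / (h * w)


def oracle_conv3x3_replicate(grid, kernel):
    h, w = grid.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(3):
                for dj in range(3):
                    si = min(max(i + di - 1, 0), h - 1)
                    sj = min(max(j + dj - 1, 0), w - 1)
                    acc += kernel[di, dj] * grid[si, sj]
            out[i, j] = acc
    return out


def oracle_edge_loss(output, lum, kernel):
    return oracle_mse(
        oracle_conv3x3_replicate(output, kernel),
        oracle_conv3x3_replicate(lum, kernel),
    )


def oracle_block_mean(grid, m):
    h, w = grid.shape
    out = np.zeros((h // m, w // m))
    for bi in range(h // m):
        for bj in range(w // m):
            acc = 0.0
            for i in range(m):
                for j in range(m):
                    acc += grid[bi * m + i, bj * m + j]
            out[bi, bj] = acc / (m * m)
    return out


def oracle_bilinear(grid, m):
    """Half-pixel-center bilinear enlargement, evaluated pointwise."""
    h, w = grid.shape
    out = np.zeros((h * m, w * m))
    for oi in range(h * m):
        for oj in range(w * m):
            si = min(max((oi + 0.5) / m - 0.5, 0.0), h - 1.0)
            sj = min(max((oj + 0.5) / m - 0.5, 0.0), w - 1.0)
            i0, j0 = int(np.floor(si)), int(np.floor(sj))
            i0, j0 = min(i0, h - 2) if h > 1 else 0, min(j0, w - 2) if w > 1 else 0
            i1, j1 = (i0 + 1, j0 + 1) if h > 1 and w > 1 else (i0, j0)
            fi, fj = si - i0, sj - j0
            out[oi, oj] = (
                grid[i0, j0] * (1 - fi) * (1 - fj)
                + grid[i0, j1] * (1 - fi) * fj
                + grid[i1, j0] * fi * (1 - fj)
                + grid[i1, j1] * fi * fj
            )
    return out
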