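"""Loss functions for single-pair fusion training.

Three pieces: the pixelwise MSE between the network output and the
interpolated ion target; the edge perceptual loss — the MSE between
edge-filtered versions of the output and the microscopy luminance, computed
with a designated 3x3 kernel; and their weighted sum

    L = w1 * L_mse + w2 * L_edge.

The edge convolution uses replicate (edge) padding so the image border does
not manufacture phantom edges, and the kernel is applied as written
(cross-correlation); the default 4-neighbor Laplacian is symmetric so the
flip convention is moot, and the Sobel options document their orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "EdgeKernel",
    "LossWeights",
    "mse_loss",
    "edge_perceptual_loss",
    "total_loss",
    "conv3x3_replicate",
    "conv3x3_replicate_adjoint",
    "FeatureExtractor",
]

_NAMED_KERNELS: dict[str, np.ndarray] = {
    # canonical single-kernel edge extractor: 4-neighbor Laplacian, zero-sum
    "laplacian4": np.array([[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]]),
    "laplacian8": np.array([[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]]),
    # horizontal-gradient Sobel (responds to vertical edges), applied unflipped
    "sobel_x": np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]),
    "sobel_y": np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]),
}

#: hook type for a perceptual-loss-style metric built on any feature map
FeatureExtractor = Callable[[np.ndarray], np.ndarray]


@dataclass
class EdgeKernel:
    """The designated 3x3 edge-extraction kernel of the edge perceptual loss."""

    weights: np.ndarray = field(
        default_factory=lambda: _NAMED_KERNELS["laplacian4"].copy()
    )
    name: str = "laplacian4"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (3, 3):
            raise ValueError("edge kernel must be exactly 3x3")

    @classmethod
    def from_name(cls, name: str) -> "EdgeKernel":
        if name not in _NAMED_KERNELS:
            raise ValueError(f"unknown kernel {name!r}; choose from {sorted(_NAMED_KERNELS)}")
        return cls(weights=_NAMED_KERNELS[name].copy(), name=name)


@dataclass
class LossWeights:
    """Multipliers (w1, w2) of the MSE and edge perceptual losses."""

    w1: float = 1.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be non-negative")

    def require_trainable(self) -> None:
        if self.w1 == 0 and self.w2 == 0:
            raise ValueError("loss weights (0, 0) admit no training signal")


def conv3x3_replicate(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size 3x3 cross-correlation with replicate (edge) padding."""
    grid = np.asarray(grid, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    pad = np.pad(grid, 1, mode="edge")
    h, w = grid.shape
    out = np.zeros_like(grid)
    for di in range(3):
        for dj in range(3):
            out += k[di, dj] * pad[di : di + h, dj : dj + w]
    return out


def conv3x3_replicate_adjoint(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint (transpose) of :func:`conv3x3_replicate` as a linear operator.

    Needed for the gradient of the edge loss: scatter each output's kernel
    footprint back onto the padded grid, then fold the padded border rows and
    columns onto the edge pixels (the adjoint of replicate padding).
    """
    grid = np.asarray(grid, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    h, w = grid.shape
    dpad = np.zeros((h + 2, w + 2), dtype=np.float64)
    for di in range(3):
        for dj in range(3):
            dpad[di : di + h, dj : dj + w] += k[di, dj] * grid
    out = dpad[1:-1, 1:-1].copy()
    out[0, :] += dpad[0, 1:-1]
    out[-1, :] += dpad[-1, 1:-1]
    out[:, 0] += dpad[1:-1, 0]
    out[:, -1] += dpad[1:-1, -1]
    out[0, 0] += dpad[0, 0]
    out[0, -1] += dpad[0, -1]
    out[-1, 0] += dpad[-1, 0]
    out[-1, -1] += dpad[-1, -1]
    return out


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Mean squared per-pixel difference, N = total pixel count."""
    output = np.asarray(output, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(output, target)
    return float(np.mean((output - target) ** 2))


def edge_perceptual_loss(
    output: np.ndarray,
    microscopy_lum: np.ndarray,
    kernel: EdgeKernel | np.ndarray | None = None,
) -> float:
    """MSE between edge-filtered output and edge-filtered microscopy luminance.

    Both grids are convolved with the designated 3x3 kernel (same-size output,
    replicate padding); the mean runs over all M = H*W output pixels.
    """
    if kernel is None:
        kernel = EdgeKernel()
    k = kernel.weights if isinstance(kernel, EdgeKernel) else np.asarray(kernel)
    output = np.asarray(output, dtype=np.float64)
    microscopy_lum = np.asarray(microscopy_lum, dtype=np.float64)
    _check_shapes(output, microscopy_lum)
    return mse_loss(conv3x3_replicate(output, k), conv3x3_replicate(microscopy_lum, k))


def total_loss(
    output: np.ndarray,
    target: np.ndarray,
    microscopy_lum: np.ndarray,
    kernel: EdgeKernel | np.ndarray | None = None,
    weights: LossWeights | tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float, float]:
    """Weighted sum w1*L_mse + w2*L_edge.

    Returns ``(L_total, L_mse, L_edge)`` — the components are always computed
    and reported individually even when their weight is zero, so a (1, 0) run
    still records the edge loss trace.
    """
    w = weights if isinstance(weights, LossWeights) else LossWeights(*weights)
    l_mse = mse_loss(output, target)
    l_edge = edge_perceptual_loss(output, microscopy_lum, kernel)
    return w.w1 * l_mse + w.w2 * l_edge, l_mse, l_edge


def edge_loss_gradient(
    output: np.ndarray,
    microscopy_lum: np.ndarray,
    kernel: EdgeKernel | np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of :func:`edge_perceptual_loss` with respect to ``output``.

    d/dy mean((Ky - Kx)^2) = (2/M) * K^T (Ky - Kx), with K^T the adjoint of
    the replicate-padded correlation.
    """
    if kernel is None:
        kernel = EdgeKernel()
    k = kernel.weights if isinstance(kernel, EdgeKernel) else np.asarray(kernel)
    output = np.asarray(output, dtype=np.float64)
    microscopy_lum = np.asarray(microscopy_lum, dtype=np.float64)
    _check_shapes(output, microscopy_lum)
    resid = conv3x3_replicate(output, k) - conv3x3_replicate(microscopy_lum, k)
    return conv3x3_replicate_adjoint(resid, k) * (2.0 / output.size)
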