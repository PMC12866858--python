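"""The loss-controlled residual network (LCRN) and a 3-layer CNN baseline.

The fusion model is small enough (≈32k parameters, one image per batch) that
it is implemented directly on numpy arrays with hand-written reverse-mode
gradients: each layer caches what its backward pass needs, and the model walks
the layers in reverse.  Correctness of every gradient is pinned against
central finite differences in the test suite.

Architecture (channels 3 -> 64 -> 32 -> 1):

* initialization block — one 3x3 convolution 3->64 + ReLU;
* residual block k — two 3x3 convolutions (in->out, out->out) with ReLU after
  the first, plus a parallel 1x1 convolution in->out; the block output is the
  sum of the two paths, ReLU-activated after block 1 and left linear after
  block 2 (a terminal ReLU would forbid negative pre-clip values and stall
  early training on normalized targets).

All convolutions keep the spatial size (replicate padding, so the border does
not inject dark-frame edges into the edge perceptual loss).  The baseline is
three plain 3x3 convolutions 3->64->32->1 with ReLUs between, no skips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .preprocess import RegisteredPair

__all__ = [
    "NetworkSpec",
    "FusedImage",
    "Conv2d",
    "ResidualBlock",
    "ResidualFusionNet",
    "CNNBaseline",
    "build_network",
    "build_cnn_baseline",
    "forward",
]


@dataclass
class NetworkSpec:
    """Declarative description of the residual fusion network."""

    in_channels: int = 3
    block_channels: tuple[int, ...] = (64, 32, 1)
    kernel_size: int = 3
    skip_kernel_size: int = 1
    activation: str = "relu"
    final_activation: str | None = None

    def __post_init__(self) -> None:
        self.block_channels = tuple(int(c) for c in self.block_channels)
        if self.in_channels != 3:
            raise ValueError("the fusion network takes a 3-channel image")
        if self.block_channels[-1] != 1:
            raise ValueError("the last block must output a single channel")
        if self.kernel_size % 2 == 0 or self.skip_kernel_size % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.activation != "relu" or self.final_activation not in (None, "relu"):
            raise ValueError("only relu / linear activations are supported")

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "block_channels": list(self.block_channels),
            "kernel_size": self.kernel_size,
            "skip_kernel_size": self.skip_kernel_size,
            "activation": self.activation,
            "final_activation": self.final_activation,
        }


@dataclass
class FusedImage:
    """Single-channel high-resolution model output with provenance."""

    values: np.ndarray
    config_hash: str = ""
    epoch_of_best: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("fused image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused image contains non-finite values")

    def clipped(self) -> np.ndarray:
        """Export copy clipped to [0, 1]; the raw values stay unclipped."""
        return np.clip(self.values, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d:
    """k x k same-size convolution with replicate padding on (C, H, W) arrays.

    He-normal initialization from the supplied Generator; ``backward``
    accumulates ``dW``/``db`` and returns the gradient w.r.t. the input.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), mode="edge") if pad else x
        # im2col: column order (channel, di, dj) matches W.reshape(O, -1)
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = windows.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = (cols @ wmat.T + self.b).T.reshape(-1, h, w)
        self._cache = (cols, (c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (c, h, w) = self._cache
        k, pad = self.k, self.k // 2
        o = dy.shape[0]
        dy_flat = dy.reshape(o, h * w)
        self.db = dy.sum(axis=(1, 2))
        self.dW = (dy_flat @ cols).reshape(self.W.shape)
        dcols = dy_flat.T @ self.W.reshape(o, -1)  # (H*W, C*k*k)
        dpatches = dcols.reshape(h, w, c, k, k)
        dxp = np.zeros((c, h + 2 * pad, w + 2 * pad))
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w] += dpatches[:, :, :, di, dj].transpose(2, 0, 1)
        if pad == 0:
            return dxp
        # adjoint of replicate padding: fold padded strips onto the edge pixels
        tmp = dxp[:, pad : pad + h, :].copy()
        tmp[:, 0, :] += dxp[:, :pad, :].sum(axis=1)
        tmp[:, -1, :] += dxp[:, pad + h :, :].sum(axis=1)
        dx = tmp[:, :, pad : pad + w].copy()
        dx[:, :, 0] += tmp[:, :, :pad].sum(axis=2)
        dx[:, :, -1] += tmp[:, :, pad + w :].sum(axis=2)
        return dx

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ResidualBlock:
    """conv3x3 -> ReLU -> conv3x3, summed with a parallel 1x1-conv skip."""

    def __init__(self, in_ch: int, out_ch: int, k: int, skip_k: int,
                 rng: np.random.Generator, final_relu: bool):
        self.conv1 = Conv2d(in_ch, out_ch, k, rng)
        self.act1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, k, rng)
        self.skip = Conv2d(in_ch, out_ch, skip_k, rng)
        self.act_out = ReLU() if final_relu else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        y = y + self.skip.forward(x)
        return self.act_out.forward(y) if self.act_out is not None else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.act_out is not None:
            dy = self.act_out.backward(dy)
        dx_main = self.conv1.backward(self.act1.backward(self.conv2.backward(dy)))
        dx_skip = self.skip.backward(dy)
        return dx_main + dx_skip

    def layers(self) -> list[Conv2d]:
        return [self.conv1, self.conv2, self.skip]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class _SequentialModel:
    """Common parameter plumbing for both fusion models."""

    def __init__(self) -> None:
        self._convs: list[Conv2d] = []

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for conv in self._convs:
            out.extend([conv.W, conv.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for conv in self._convs:
            out.extend([conv.dW, conv.db])
        return out

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self._convs)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s


class ResidualFusionNet(_SequentialModel):
    """Initialization block + two residual blocks, channels 3->64->32->1."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        chans = [self.spec.in_channels, *self.spec.block_channels]
        self.init_conv = Conv2d(chans[0], chans[1], self.spec.kernel_size, rng)
        self.init_act = ReLU()
        self.blocks = []
        n_blocks = len(chans) - 2
        for i in range(n_blocks):
            final_relu = (i < n_blocks - 1) or self.spec.final_activation == "relu"
            self.blocks.append(
                ResidualBlock(chans[i + 1], chans[i + 2], self.spec.kernel_size,
                              self.spec.skip_kernel_size, rng, final_relu)
            )
        self._convs = [self.init_conv]
        for blk in self.blocks:
            self._convs.extend(blk.layers())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(3, H, W) image -> (H, W) raw (unclipped) fused output."""
        y = self.init_act.forward(self.init_conv.forward(x))
        for blk in self.blocks:
            y = blk.forward(y)
        return y[0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = dout[None, :, :]
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return self.init_conv.backward(self.init_act.backward(dy))


class CNNBaseline(_SequentialModel):
    """Plain three-layer CNN 3->64->32->1 with ReLUs between, no skips."""

    def __init__(self, seed: int = 0, kernel_size: int = 3):
        super().__init__()
        rng = np.random.default_rng(seed)
        chans = [3, 64, 32, 1]
        self._acts: list[ReLU | None] = []
        for i in range(3):
            self._convs.append(Conv2d(chans[i], chans[i + 1], kernel_size, rng))
            self._acts.append(ReLU() if i < 2 else None)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for conv, act in zip(self._convs, self._acts):
            y = conv.forward(y)
            if act is not None:
                y = act.forward(y)
        return y[0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = dout[None, :, :]
        for conv, act in zip(reversed(self._convs), reversed(self._acts)):
            if act is not None:
                dy = act.backward(dy)
            dy = conv.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Builders and full-image forward
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> ResidualFusionNet:
    """Build the seeded residual fusion network."""
    return ResidualFusionNet(spec, seed)


def build_cnn_baseline(seed: int = 0) -> CNNBaseline:
    """Build the seeded 3-layer CNN comparison baseline."""
    return CNNBaseline(seed)


def forward(model, pair: RegisteredPair, config_hash: str = "",
            epoch: int = 0) -> FusedImage:
    """Full-image forward pass (single sample, no patching).

    The raw output is kept unclipped; :meth:`FusedImage.clipped` produces the
    export copy.
    """
    x = np.ascontiguousarray(pair.microscopy.values.transpose(2, 0, 1))
    y = model.forward(x)
    if y.shape != pair.microscopy.spatial_shape:
        raise ValueError(
            f"model output {y.shape} does not match pair {pair.microscopy.spatial_shape}"
        )
    return FusedImage(values=y, config_hash=config_hash, epoch_of_best=epoch)


def config_hash(obj: dict) -> str:
    """Stable hash of a canonicalized (key-sorted) configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
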